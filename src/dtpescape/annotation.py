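"""Gene-model containers and GTF serialization.

Transcripts are stored with 0-based half-open exon coordinates internally;
GTF output follows the format's 1-based inclusive convention. Each
transcript carries a boolean ``high_confidence`` flag (serialized as a GTF
attribute), the hook used to restrict 3'-end quantification to well-trusted
gene models.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils

__all__ = ["Transcript", "TranscriptAnnotation"]


@dataclass(frozen=True)
class Transcript:
    """A transcript: ordered exons on one strand of one chromosome.

    ``exons`` are 0-based half-open ``(start, end)`` intervals stored in
    genomic order, non-overlapping.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    high_confidence: bool = True

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id!r} has zero exons")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if e <= s or s < 0:
                raise ValueError(f"bad exon ({s}, {e}) in {self.transcript_id!r}")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping exons in {self.transcript_id!r}")
        object.__setattr__(self, "exons", exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exons_5to3(self) -> tuple[tuple[int, int], ...]:
        """Exons ordered 5' to 3' in transcript orientation."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))


@dataclass(frozen=True)
class TranscriptAnnotation:
    """An ordered collection of transcripts grouped into genes."""

    transcripts: tuple[Transcript, ...]

    def __post_init__(self):
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("transcript ids must be unique")

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.transcripts:
            seen.setdefault(t.gene_id, None)
        return list(seen)

    def by_gene(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            out.setdefault(t.gene_id, []).append(t)
        return out

    def high_confidence(self) -> "TranscriptAnnotation":
        return TranscriptAnnotation(
            tuple(t for t in self.transcripts if t.high_confidence)
        )

    # ---- GTF round trip -------------------------------------------------

    def to_gtf(self, path: str | Path) -> None:
        """Write exon records in GTF (1-based, inclusive)."""
        with open(path, "w") as fh:
            fh.write(self.to_gtf_string())

    def to_gtf_string(self) -> str:
        lines = []
        for t in self.transcripts:
            flag = "true" if t.high_confidence else "false"
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'high_confidence "{flag}";'
            )
            for s, e in t.exons:
                lines.append(
                    f"{t.chrom}\tdtpescape\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}"
                )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_gtf(cls, path: str | Path) -> "TranscriptAnnotation":
        with open(path) as fh:
            return cls.from_gtf_string(fh.read())

    @classmethod
    def from_gtf_string(cls, text: str) -> "TranscriptAnnotation":
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        grouped: dict[str, dict] = {}
        for feat in db.features_of_type("exon", order_by=("seqid", "start")):
            tid = feat.attributes["transcript_id"][0]
            rec = grouped.setdefault(
                tid,
                {
                    "gene_id": feat.attributes["gene_id"][0],
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "high_confidence": feat.attributes.get(
                        "high_confidence", ["true"]
                    )[0].lower()
                    == "true",
                    "exons": [],
                },
            )
            rec["exons"].append((feat.start - 1, feat.end))  # to 0-based half-open
        transcripts = tuple(
            Transcript(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(rec["exons"]),
                high_confidence=rec["high_confidence"],
            )
            for tid, rec in grouped.items()
        )
        return cls(transcripts=transcripts)
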