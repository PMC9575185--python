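"""Readers/writers for the plain-text formats the pipeline exchanges.

Reads travel as BED6 (0-based half-open; the ``name`` field carries the
cell/sample id) or SAM (cell id in the ``RG`` tag; unmapped records are
skipped). Matrices and cohort tables are TSV. GTF serialization lives on
:class:`~dtpescape.annotation.TranscriptAnnotation`.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .genome import GenomeSpec

__all__ = [
    "write_bed6",
    "read_bed6",
    "write_sam",
    "read_sam",
    "write_matrix",
    "read_matrix",
]


def write_bed6(reads: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["start"],
            "end": reads["end"],
            "name": reads["cell_id"],
            "score": 0,
            "strand": reads["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "strand": df["strand"],
            "cell_id": df["name"],
        }
    )


def write_sam(reads: pd.DataFrame, genome: GenomeSpec, path: str | Path) -> None:
    """Write reads as mapped SAM records (read-group = cell id, no sequence)."""
    cells = list(pd.unique(reads["cell_id"]))
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome.chromosomes],
        "RG": [{"ID": str(c)} for c in cells],
    }
    ref_ids = {name: i for i, (name, _) in enumerate(genome.chromosomes)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, row in enumerate(reads.itertuples(index=False)):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"r{i}"
            a.reference_id = ref_ids[row.chrom]
            a.reference_start = int(row.start)
            a.mapping_quality = 60
            a.cigartuples = [(0, int(row.end) - int(row.start))]
            a.flag = 16 if row.strand == "-" else 0
            a.set_tag("RG", str(row.cell_id))
            fh.write(a)


def read_sam(path: str | Path) -> pd.DataFrame:
    """Read mapped SAM records into the BED-like frame; unmapped are skipped."""
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            rows.append(
                (
                    a.reference_name,
                    a.reference_start,
                    a.reference_end,
                    "-" if a.is_reverse else "+",
                    a.get_tag("RG") if a.has_tag("RG") else "sample",
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "cell_id"])


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
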