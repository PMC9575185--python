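"""Synthetic-data generators for every input the analysis pipeline consumes.

Four generators cover the pipeline's input space:

``gen_sc_coverage``
    Sparse single-cell genomic read coverage over an (optionally aneuploid)
    baseline with planted multi-megabase amplifications/deletions. Expected
    local read density is proportional to local copy number; counts are
    overdispersed (negative-binomial marginals) through a per-cell
    gamma-distributed size factor — the dominant overdispersion source in
    shallow single-cell libraries, and the component the per-cell
    percentile normalization downstream is designed to absorb.

``gen_annotation``
    A toy non-overlapping gene annotation with per-transcript
    high-confidence flags, writable as GTF.

``gen_rnaseq_reads``
    Directional RNA-seq reads with tunable 3' degradation bias: the
    probability that a fragment ending at distance ``d`` from a
    transcript's 3' end survives decays as ``exp(-degradation_rate * d)``.
    Rate 0 recovers uniform coverage.

``gen_resistance_cohort``
    Per-culture time-to-first-resistant-colony records, either from the
    mechanistic escape simulator or from simple exponential hazards.

All generators are bit-reproducible for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Transcript, TranscriptAnnotation
from .genome import GenomeSpec

__all__ = [
    "PlantedCNV",
    "CoverageSim",
    "gen_sc_coverage",
    "gen_annotation",
    "gen_rnaseq_reads",
    "gen_resistance_cohort",
]

READ_COLUMNS = ["chrom", "start", "end", "strand", "cell_id"]


@dataclass(frozen=True)
class PlantedCNV:
    """A copy-number change planted into a subset of cells.

    ``copy_delta`` is the signed change in copies relative to the baseline
    ploidy; carriers are listed in ``cell_ids``.
    """

    chrom: str
    start: int
    end: int
    copy_delta: int
    cell_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.end - self.start <= 0:
            raise ValueError("CNV must have positive length")
        object.__setattr__(self, "cell_ids", frozenset(self.cell_ids))


@dataclass
class CoverageSim:
    """Reads plus ground truth from :func:`gen_sc_coverage`.

    ``reads``: BED-like frame (chrom, start, end, strand, cell_id).
    ``segments``: per (cell, constant-copy-number segment) truth rows.
    ``carriers``: per (cell, planted CNV) carrier flags.
    """

    reads: pd.DataFrame
    segments: pd.DataFrame
    carriers: pd.DataFrame
    cell_ids: list[str]


def _cell_segments(genome: GenomeSpec, planted: list[PlantedCNV], cell: str):
    """Constant-copy-number segments (chrom, start, end, copies) for a cell."""
    segs = []
    for chrom, length in genome.chromosomes:
        base = genome.ploidy_of(chrom)
        cuts = {0, length}
        mine = [p for p in planted if p.chrom == chrom and cell in p.cell_ids]
        for p in mine:
            cuts.update((p.start, p.end))
        bounds = sorted(cuts)
        for s, e in zip(bounds, bounds[1:]):
            cn = base + sum(p.copy_delta for p in mine if p.start <= s and e <= p.end)
            if cn < 0:
                raise ValueError(
                    f"planted CNVs drive copy number below zero on {chrom} for {cell}"
                )
            segs.append((chrom, s, e, cn))
    return segs


def gen_sc_coverage(
    genome: GenomeSpec,
    planted: list[PlantedCNV],
    n_cells: int,
    mean_reads_per_cell: float,
    dispersion: float = 0.2,
    seed: int | None = None,
    read_length: int = 75,
    cell_prefix: str = "cell",
    window_efficiency_sd: float = 0.0,
    efficiency_tile: int = 2_500_000,
    aberrant_regions: list[tuple[str, int, int, float]] | None = None,
) -> CoverageSim:
    """Simulate sparse single-cell genomic coverage with planted CNVs.

    Expected read density in a region is proportional to that cell's local
    copy number. Per-cell totals fluctuate with a gamma size factor of
    shape ``1/dispersion`` (mean 1, variance ``dispersion``), which makes
    marginal binned counts negative binomial with the stated dispersion.

    ``window_efficiency_sd > 0`` additionally draws one log-normal read
    capture efficiency per ``efficiency_tile`` genomic tile, shared by all
    cells — emulating the mappability/GC capture bias of real genomes that
    per-window median centring downstream is designed to remove (and that
    gives the aberrant-window filter genuine extremes to catch). The
    default of 0 keeps density exactly proportional to copy number.

    ``aberrant_regions`` plants centromere/low-complexity-like artefacts:
    ``(chrom, start, end, multiplier)`` regions whose capture efficiency
    is multiplied for every cell alike (e.g. multiplier 5 for a
    repeat-pileup region, 0.05 for an unmappable one) — the shared
    coverage artefacts the aberrant-window exclusion step is meant to
    remove.
    """
    if mean_reads_per_cell <= 0:
        raise ValueError("mean_reads_per_cell must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    for p in planted:
        if not genome.contains(p.chrom, p.start, p.end):
            raise ValueError(
                f"planted CNV {p.chrom}:{p.start}-{p.end} lies outside the genome"
            )
        if genome.ploidy_of(p.chrom) + p.copy_delta < 0:
            raise ValueError("baseline ploidy + copy_delta must be >= 0")
    rng = np.random.default_rng(seed)
    cells = [f"{cell_prefix}{i:03d}" for i in range(n_cells)]
    baseline_mass = sum(
        genome.ploidy_of(c) * ln for c, ln in genome.chromosomes
    )
    chrom_len = genome.lengths

    # shared per-tile capture efficiencies (identical for every cell)
    efficiency: dict[str, np.ndarray] = {}
    for chrom, ln in genome.chromosomes:
        n_tiles = -(-ln // efficiency_tile)
        if window_efficiency_sd > 0:
            eff = rng.lognormal(0.0, window_efficiency_sd, size=n_tiles)
        else:
            eff = np.ones(n_tiles)
        efficiency[chrom] = eff
    for chrom, rs, re_, mult in aberrant_regions or []:
        if not genome.contains(chrom, rs, re_):
            raise ValueError(f"aberrant region {chrom}:{rs}-{re_} outside genome")
        t0, t1 = rs // efficiency_tile, (re_ - 1) // efficiency_tile
        efficiency[chrom][t0 : t1 + 1] *= float(mult)
    mean_eff = float(
        np.concatenate(list(efficiency.values())).mean()
    )

    chroms, starts, strands, cell_col = [], [], [], []
    seg_rows = []
    for cell in cells:
        g = rng.gamma(1.0 / dispersion, dispersion) if dispersion > 0 else 1.0
        for chrom, s, e, cn in _cell_segments(genome, planted, cell):
            seg_rows.append((cell, chrom, s, e, cn))
            eff = efficiency[chrom]
            # split the segment at tile boundaries so efficiency applies
            t0, t1 = s // efficiency_tile, (e - 1) // efficiency_tile
            bounds = [s] + [
                (ti + 1) * efficiency_tile for ti in range(t0, t1)
            ] + [e]
            for ps, pe in zip(bounds, bounds[1:]):
                lam = (
                    g
                    * mean_reads_per_cell
                    * cn
                    * (eff[ps // efficiency_tile] / mean_eff)
                    * (pe - ps)
                    / baseline_mass
                )
                k = rng.poisson(lam)
                if k == 0:
                    continue
                pos = rng.integers(ps, pe, size=k)
                chroms.append(np.repeat(chrom, k))
                starts.append(pos)
                strands.append(rng.choice(["+", "-"], size=k))
                cell_col.append(np.repeat(cell, k))

    if starts:
        start_arr = np.concatenate(starts)
        chrom_arr = np.concatenate(chroms)
        end_arr = np.minimum(
            start_arr + read_length,
            np.array([chrom_len[c] for c in chrom_arr]),
        )
        reads = pd.DataFrame(
            {
                "chrom": chrom_arr,
                "start": start_arr,
                "end": end_arr,
                "strand": np.concatenate(strands),
                "cell_id": np.concatenate(cell_col),
            }
        )
    else:
        reads = pd.DataFrame(columns=READ_COLUMNS)

    segments = pd.DataFrame(
        seg_rows, columns=["cell_id", "chrom", "start", "end", "copy_number"]
    )
    carriers = pd.DataFrame(
        [
            (cell, p.chrom, p.start, p.end, p.copy_delta, cell in p.cell_ids)
            for p in planted
            for cell in cells
        ],
        columns=["cell_id", "chrom", "start", "end", "copy_delta", "carrier"],
    )
    return CoverageSim(reads=reads, segments=segments, carriers=carriers, cell_ids=cells)


def gen_annotation(
    genome: GenomeSpec,
    n_genes: int,
    transcripts_per_gene: int = 1,
    exon_structure_rule: dict | None = None,
    high_conf_fraction: float = 1.0,
    seed: int | None = None,
    intergenic_gap: tuple[int, int] = (500, 2000),
) -> TranscriptAnnotation:
    """Generate a non-overlapping toy gene annotation.

    ``exon_structure_rule`` gives inclusive ranges for the per-transcript
    structure: ``{"n_exons": (lo, hi), "exon_len": (lo, hi),
    "intron_len": (lo, hi)}``. Additional transcripts of a gene share its
    3' end (they are 5'-truncations of the primary transcript). A fraction
    ``high_conf_fraction`` of transcripts is flagged high-confidence.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= high_conf_fraction <= 1.0:
        raise ValueError("high_conf_fraction must be in [0, 1]")
    rule = {"n_exons": (1, 1), "exon_len": (800, 2500), "intron_len": (200, 800)}
    rule.update(exon_structure_rule or {})
    rng = np.random.default_rng(seed)

    transcripts: list[Transcript] = []
    chrom_iter = list(genome.chromosomes)
    ci = 0
    cursor = 0
    for gi in range(n_genes):
        n_ex = int(rng.integers(rule["n_exons"][0], rule["n_exons"][1] + 1))
        exon_lens = rng.integers(
            rule["exon_len"][0], rule["exon_len"][1] + 1, size=n_ex
        )
        intron_lens = (
            rng.integers(rule["intron_len"][0], rule["intron_len"][1] + 1, size=n_ex - 1)
            if n_ex > 1
            else np.array([], dtype=int)
        )
        span = int(exon_lens.sum() + intron_lens.sum())
        gap = int(rng.integers(*intergenic_gap))
        # advance to a chromosome with room
        placed = False
        while ci < len(chrom_iter):
            name, length = chrom_iter[ci]
            if cursor + gap + span <= length:
                placed = True
                break
            ci += 1
            cursor = 0
        if not placed:
            raise ValueError(
                f"infeasible packing: gene {gi} (span {span} bp) does not fit "
                "in the remaining genome"
            )
        start = cursor + gap
        exons = []
        pos = start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        cursor = pos
        strand = str(rng.choice(["+", "-"]))
        gene_id = f"G{gi:04d}"
        primary = Transcript(
            transcript_id=f"{gene_id}.1",
            gene_id=gene_id,
            chrom=name,
            strand=strand,
            exons=tuple(exons),
            high_confidence=bool(rng.random() < high_conf_fraction),
        )
        transcripts.append(primary)
        for k in range(1, transcripts_per_gene):
            ex53 = list(primary.exons_5to3())
            if len(ex53) > 1:
                trimmed = ex53[1:]  # drop 5'-most exon; 3' end shared
            else:
                s, e = ex53[0]
                keep = int(rng.integers(100, max(101, (e - s) // 2 + 1)))
                trimmed = [(e - keep, e)] if strand == "+" else [(s, s + keep)]
            exons_genomic = tuple(sorted(trimmed))
            transcripts.append(
                Transcript(
                    transcript_id=f"{gene_id}.{k + 1}",
                    gene_id=gene_id,
                    chrom=name,
                    strand=strand,
                    exons=exons_genomic,
                    high_confidence=bool(rng.random() < high_conf_fraction),
                )
            )
    return TranscriptAnnotation(transcripts=tuple(transcripts))


def _spliced_to_genomic(t: Transcript, lo: int, hi: int) -> list[tuple[int, int]]:
    """Map spliced interval [lo, hi) (5'->3' transcript coords) to genomic pieces."""
    pieces = []
    off = 0
    for s, e in t.exons_5to3():
        ln = e - s
        a, b = max(lo, off), min(hi, off + ln)
        if a < b:
            if t.strand == "+":
                pieces.append((s + (a - off), s + (b - off)))
            else:
                pieces.append((e - (b - off), e - (a - off)))
        off += ln
    return pieces


def gen_rnaseq_reads(
    annotation: TranscriptAnnotation,
    expression_truth: dict[str, float],
    degradation_rate: float = 0.0,
    directional: bool = True,
    n_reads: int = 100_000,
    read_length: int = 75,
    seed: int | None = None,
    sample_id: str = "S1",
) -> pd.DataFrame:
    """Simulate reads from a degraded, optionally directional RNA library.

    ``expression_truth`` maps transcript ids to non-negative abundances
    (molecule counts). A fragment whose 3' end lies ``d`` nt from the
    transcript 3' end survives degradation with probability proportional
    to ``exp(-degradation_rate * d)``; reads are sampled from the surviving
    fragment mass, so total per-transcript weight is
    ``abundance * (1 - exp(-rate * L)) / rate`` (``abundance * L`` when the
    rate is zero). Directional libraries emit each read on the strand
    opposite the transcript (dUTP-style). Reads are fixed-length and are
    kept within a single exon (a read whose fragment spans a splice
    junction is shifted into the exon holding its 3' end).

    Returns a BED-like frame (chrom, start, end, strand, cell_id, source)
    where ``cell_id`` is the sample label and ``source`` the true
    transcript of origin.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    tids = [t.transcript_id for t in annotation]
    abund = np.array([float(expression_truth.get(t, 0.0)) for t in tids])
    if (abund < 0).any():
        raise ValueError("abundances must be >= 0")
    if abund.sum() == 0:
        raise ValueError("abundances must not all be zero")
    rng = np.random.default_rng(seed)
    lengths = np.array([t.spliced_length for t in annotation], dtype=float)
    r = float(degradation_rate)
    if r > 0:
        weights = abund * (1.0 - np.exp(-r * lengths)) / r
    else:
        weights = abund * lengths
    p = weights / weights.sum()
    counts = rng.multinomial(n_reads, p)

    rows_chrom, rows_start, rows_end, rows_strand, rows_src = [], [], [], [], []
    for t, k in zip(annotation, counts):
        if k == 0:
            continue
        L = t.spliced_length
        span = max(L - read_length, 0)
        if span == 0:
            d = np.zeros(k)
            rlen = min(read_length, L)
        else:
            if r > 0:
                # truncated exponential on [0, span]
                u = rng.random(k)
                d = -np.log1p(-u * (1.0 - np.exp(-r * span))) / r
            else:
                d = rng.random(k) * span
            rlen = read_length
        d = np.floor(d).astype(int)
        lo = L - d - rlen  # spliced 5' coordinate of the read
        read_strand = (
            ("-" if t.strand == "+" else "+")
            if directional
            else None
        )
        ex53 = t.exons_5to3()
        # exon boundaries in spliced coordinates
        offs = np.cumsum([0] + [e - s for s, e in ex53])
        for lo_i in lo:
            hi_i = lo_i + rlen
            pieces = _spliced_to_genomic(t, int(lo_i), int(hi_i))
            if len(pieces) > 1:
                # slide the read into the exon containing its 3' end
                j = int(np.searchsorted(offs, hi_i, side="left")) - 1
                s, e = ex53[j]
                if e - s >= rlen:
                    anchor = pieces[-1][0] if t.strand == "+" else pieces[0][0]
                    gs = max(s, min(e - rlen, anchor))
                    piece = (gs, gs + rlen)
                else:
                    piece = (s, e)
            else:
                piece = pieces[0]
            rows_chrom.append(t.chrom)
            rows_start.append(piece[0])
            rows_end.append(piece[1])
            rows_strand.append(
                read_strand if read_strand is not None else str(rng.choice(["+", "-"]))
            )
            rows_src.append(t.transcript_id)
    reads = pd.DataFrame(
        {
            "chrom": rows_chrom,
            "start": rows_start,
            "end": rows_end,
            "strand": rows_strand,
            "cell_id": sample_id,
            "source": rows_src,
        }
    )
    return reads


def gen_resistance_cohort(
    group_params: dict,
    n_cultures: int,
    max_weeks: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-culture time-to-resistance records for one or more groups.

    ``group_params`` maps a group label either to a float — an exponential
    hazard per week for the waiting time to the first resistant colony —
    or to an :class:`~dtpescape.escape.EscapeParams`, in which case each
    culture runs the mechanistic simulator. Cultures without a colony by
    ``max_weeks`` are right-censored there.

    Returns a frame with columns (culture_id, group, time_weeks, event).
    """
    from .escape import EscapeParams, simulate_culture

    if n_cultures < 1:
        raise ValueError("n_cultures must be >= 1")
    if max_weeks <= 0:
        raise ValueError("max_weeks must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, par in group_params.items():
        if isinstance(par, EscapeParams):
            for i in range(n_cultures):
                sub = int(rng.integers(0, 2**31 - 1))
                out = simulate_culture(
                    par, horizon_weeks=max_weeks, seed=sub, stop_at_first_colony=True
                )
                t = out.t_colony if out.resistant else max_weeks
                rows.append((f"{group}_{i:04d}", group, min(t, max_weeks),
                             int(out.resistant and out.t_colony <= max_weeks)))
        else:
            hazard = float(par)
            if hazard < 0:
                raise ValueError("hazard must be >= 0")
            if hazard == 0:
                t = np.full(n_cultures, np.inf)
            else:
                t = rng.exponential(1.0 / hazard, size=n_cultures)
            for i, ti in enumerate(t):
                event = int(ti <= max_weeks)
                rows.append((f"{group}_{i:04d}", group, min(ti, max_weeks), event))
    return pd.DataFrame(rows, columns=["culture_id", "group", "time_weeks", "event"])
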