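"""Single-cell copy-number profiling from binned read counts.

The pipeline mirrors how shallow single-cell sequencing coverage is turned
into per-cell copy-number calls:

1. Reads are counted in wide overlapping genomic windows (default 5 Mb
   wide, spaced every 2.5 Mb) — :func:`make_window_grid`,
   :func:`count_reads_in_windows`.
2. Windows with aberrantly high or low total coverage (centromeres,
   low-complexity regions) are excluded — :func:`filter_aberrant_windows`.
3. Counts are log2-transformed, median-centred per window across cells
   (yielding log2 fold change in copy number relative to the population
   average), and each cell is distribution-matched to a common reference
   through a two-anchor percentile ("enrichment") normalization —
   :func:`normalize_copy_profiles`, :func:`enrichment_normalize`.
4. Large copy-number events are called per cell by thresholding and
   merging consecutive aberrant windows — :func:`call_cnv_events` — and
   summarized per cell group in a 2x2 contingency table —
   :func:`event_contingency`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec

log = logging.getLogger(__name__)

__all__ = [
    "WindowGrid",
    "make_window_grid",
    "count_reads_in_windows",
    "filter_aberrant_windows",
    "enrichment_normalize",
    "normalize_copy_profiles",
    "call_cnv_events",
    "event_contingency",
]


@dataclass
class WindowGrid:
    """Fixed-width sliding windows over a genome.

    ``windows`` has columns (chrom, start, end), 0-based half-open,
    ordered by chromosome then start.
    """

    windows: pd.DataFrame
    width: int
    step: int

    def __len__(self) -> int:
        return len(self.windows)


def make_window_grid(
    genome: GenomeSpec, width: int | float = 5e6, step: int | float = 2.5e6
) -> WindowGrid:
    """Windows at starts 0, step, 2*step, ... with start + width <= length.

    The final partial window of each chromosome is dropped; chromosomes
    shorter than ``width`` contribute no windows (warned, not an error).
    """
    width, step = int(width), int(step)
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be > 0")
    if step > width:
        raise ValueError("step must be <= width (overlapping or abutting windows)")
    rows = []
    for chrom, length in genome.chromosomes:
        n = (length - width) // step + 1 if length >= width else 0
        if n == 0:
            log.warning("chromosome %s (%d bp) shorter than window width", chrom, length)
        for i in range(n):
            rows.append((chrom, i * step, i * step + width))
    return WindowGrid(
        windows=pd.DataFrame(rows, columns=["chrom", "start", "end"]),
        width=width,
        step=step,
    )


def count_reads_in_windows(
    reads: pd.DataFrame, grid: WindowGrid, cell_ids: list[str] | None = None
) -> pd.DataFrame:
    """Count reads per (cell, window) by read midpoint.

    A read is assigned to every window containing its midpoint, so with
    50%-overlapping windows interior reads are counted twice — once per
    overlapping window. Reads on chromosomes absent from the grid are
    skipped (logged). Returns a cells x windows integer frame whose
    columns are window indices into ``grid.windows``.
    """
    if cell_ids is None:
        cell_ids = sorted(pd.unique(reads["cell_id"])) if len(reads) else []
    cell_index = {c: i for i, c in enumerate(cell_ids)}
    mat = np.zeros((len(cell_ids), len(grid)), dtype=np.int64)
    if len(reads):
        win = grid.windows
        offsets = {}
        nwin = {}
        for chrom, sub in win.groupby("chrom", sort=False):
            offsets[chrom] = int(sub.index[0])
            nwin[chrom] = len(sub)
        unknown = 0
        n_cover = -(-grid.width // grid.step)  # ceil
        for chrom, sub in reads.groupby("chrom", sort=False):
            if chrom not in offsets:
                unknown += len(sub)
                continue
            mid = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(
                np.int64
            )
            cells = np.array(
                [cell_index.get(c, -1) for c in sub["cell_id"]], dtype=np.int64
            )
            if (cells < 0).any():
                raise ValueError("reads carry cell ids missing from the cell roster")
            i_hi = mid // grid.step
            for j in range(n_cover):
                i = i_hi - j
                ok = (
                    (i >= 0)
                    & (i < nwin[chrom])
                    & (i * grid.step <= mid)
                    & (mid < i * grid.step + grid.width)
                )
                if ok.any():
                    np.add.at(mat, (cells[ok], offsets[chrom] + i[ok]), 1)
        if unknown:
            log.info("skipped %d reads on chromosomes absent from the grid", unknown)
    return pd.DataFrame(mat, index=pd.Index(cell_ids, name="cell_id"))


def filter_aberrant_windows(
    matrix: pd.DataFrame, low_quantile: float = 0.05, high_quantile: float = 0.99
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mask windows with aberrant total coverage across cells.

    A window is excluded when its total count over all cells lies strictly
    below the ``low_quantile`` or strictly above the ``high_quantile`` of
    window totals (linear-interpolation quantiles). Returns the unchanged
    matrix and a boolean exclusion mask over windows.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("matrix must be non-empty")
    if not (0.0 <= low_quantile < high_quantile <= 1.0):
        raise ValueError("require 0 <= low_quantile < high_quantile <= 1")
    totals = matrix.to_numpy().sum(axis=0)
    q_lo, q_hi = np.quantile(totals, [low_quantile, high_quantile])
    excluded = (totals < q_lo) | (totals > q_hi)
    log.info("excluded %d/%d aberrant windows", int(excluded.sum()), len(excluded))
    return matrix, excluded


def enrichment_normalize(
    values: np.ndarray | pd.DataFrame,
    anchors: tuple[float, float] = (10.0, 90.0),
    reference: tuple[float, float] | None = None,
    sample_names: list | None = None,
) -> np.ndarray | pd.DataFrame:
    """Two-anchor percentile matching across samples (rows).

    For each sample (row) the unique affine map sending its
    (``anchors[0]``, ``anchors[1]``) percentile values onto the reference
    anchor values is applied to all its values. The default reference is
    the mean of the per-sample anchor values, which makes the operation
    idempotent. The map is strictly increasing, so sample-internal order
    is preserved; after it, every sample's anchor percentiles equal the
    reference (to float tolerance).
    """
    p_lo, p_hi = anchors
    if not (0.0 <= p_lo < p_hi <= 100.0):
        raise ValueError("anchors must satisfy 0 <= p_lo < p_hi <= 100")
    is_frame = isinstance(values, pd.DataFrame)
    arr = values.to_numpy(dtype=float) if is_frame else np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("values must be 2-D (samples x features)")
    names = (
        list(values.index)
        if is_frame
        else (sample_names if sample_names is not None else list(range(arr.shape[0])))
    )
    lo = np.percentile(arr, p_lo, axis=1)
    hi = np.percentile(arr, p_hi, axis=1)
    degenerate = hi <= lo
    if degenerate.any():
        bad = [str(names[i]) for i in np.flatnonzero(degenerate)]
        raise ValueError(
            "degenerate sample(s) with equal anchor percentiles: " + ", ".join(bad)
        )
    if reference is None:
        ref_lo, ref_hi = float(lo.mean()), float(hi.mean())
    else:
        ref_lo, ref_hi = map(float, reference)
        if ref_hi <= ref_lo:
            raise ValueError("reference anchors must be strictly increasing")
    scale = (ref_hi - ref_lo) / (hi - lo)
    out = ref_lo + (arr - lo[:, None]) * scale[:, None]
    if is_frame:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def normalize_copy_profiles(
    matrix: pd.DataFrame,
    excluded: np.ndarray | None = None,
    pseudocount: float = 1.0,
    anchors: tuple[float, float] = (10.0, 90.0),
    percentile_normalize: bool = True,
) -> pd.DataFrame:
    """Turn binned counts into per-cell log2 copy-ratio profiles.

    Three ordered steps on retained windows: (1) ``log2(count +
    pseudocount)``; (2) per window, subtract the median across cells —
    after this the profile reads as log2 fold change in copy number
    relative to the population average; (3) per cell, two-anchor
    percentile matching (:func:`enrichment_normalize`) against the
    across-cell mean anchors, absorbing depth and distribution differences
    between cells. Excluded windows carry NaN. Cells with zero total count
    are dropped with a warning. ``percentile_normalize=False`` stops after
    step (2), where the across-cell median of every retained window is
    exactly zero.
    """
    if excluded is None:
        excluded = np.zeros(matrix.shape[1], dtype=bool)
    excluded = np.asarray(excluded, dtype=bool)
    zero_cells = matrix.sum(axis=1) == 0
    if zero_cells.any():
        log.warning(
            "dropping %d cell(s) with zero total counts: %s",
            int(zero_cells.sum()),
            list(matrix.index[zero_cells]),
        )
        matrix = matrix.loc[~zero_cells]
    retained = matrix.loc[:, ~excluded]
    vals = np.log2(retained.to_numpy(dtype=float) + pseudocount)
    vals = vals - np.median(vals, axis=0, keepdims=True)
    if percentile_normalize:
        vals = enrichment_normalize(
            vals, anchors=anchors, sample_names=list(matrix.index)
        )
    profile = pd.DataFrame(
        np.nan, index=matrix.index, columns=matrix.columns, dtype=float
    )
    profile.loc[:, ~excluded] = vals
    return profile


def call_cnv_events(
    profile: pd.DataFrame,
    grid: WindowGrid,
    amp_log2: float = 1.0,
    del_log2: float = -1.0,
    min_span: int | float = 10e6,
) -> pd.DataFrame:
    """Call large per-cell copy-number events from a normalized profile.

    Windows with value >= ``amp_log2`` (amplification) or <= ``del_log2``
    (deletion) are marked per cell; consecutive marked windows are merged
    into runs, bridging excluded (NaN) windows lying strictly inside a
    run; a run becomes an event when its genomic span (first window start
    to last window end) strictly exceeds ``min_span``.

    Returns a frame with columns (cell_id, chrom, start, end, direction,
    mean_log2, span, n_windows).
    """
    if amp_log2 < 0 or del_log2 > 0:
        raise ValueError("amp_log2 must be >= 0 and del_log2 <= 0")
    win = grid.windows
    rows = []
    values = profile.to_numpy(dtype=float)
    chrom_groups = [
        (chrom, sub.index.to_numpy()) for chrom, sub in win.groupby("chrom", sort=False)
    ]
    starts = win["start"].to_numpy()
    ends = win["end"].to_numpy()
    for ci, cell in enumerate(profile.index):
        v = values[ci]
        for direction, marked_all in (
            ("amplification", v >= amp_log2),
            ("deletion", v <= del_log2),
        ):
            for chrom, idx in chrom_groups:
                run: list[int] = []
                for w in idx:
                    if np.isnan(v[w]):
                        continue  # excluded windows bridge a run
                    if marked_all[w]:
                        run.append(w)
                    else:
                        if run:
                            rows.append((ci, cell, chrom, run, direction))
                        run = []
                if run:
                    rows.append((ci, cell, chrom, run, direction))
    events = []
    for ci, cell, chrom, run, direction in rows:
        span_start, span_end = int(starts[run[0]]), int(ends[run[-1]])
        span = span_end - span_start
        if span > min_span:
            run_vals = values[ci, run]
            events.append(
                (
                    cell,
                    chrom,
                    span_start,
                    span_end,
                    direction,
                    float(np.mean(run_vals)),
                    span,
                    len(run),
                )
            )
    return pd.DataFrame(
        events,
        columns=[
            "cell_id",
            "chrom",
            "start",
            "end",
            "direction",
            "mean_log2",
            "span",
            "n_windows",
        ],
    )


def event_contingency(
    events: pd.DataFrame, cell_groups: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """2x2 table of cells with/without >= 1 event, by group.

    Rows follow the order groups first appear in ``cell_groups``; columns
    are ``with_event`` / ``without_event``. Each cell counts once however
    many events it has. Cells appearing in ``events`` but absent from
    ``cell_groups`` are rejected.
    """
    groups = pd.Series(cell_groups)
    event_cells = set(events["cell_id"]) if len(events) else set()
    ungrouped = event_cells - set(groups.index)
    if ungrouped:
        raise ValueError(f"cells with events but no group label: {sorted(ungrouped)}")
    order = list(pd.unique(groups))
    if len(order) != 2:
        raise ValueError(f"expected exactly 2 groups, got {order}")
    table = []
    for g in order:
        members = set(groups.index[groups == g])
        with_ev = len(members & event_cells)
        table.append((with_ev, len(members) - with_ev))
    return pd.DataFrame(
        table, index=pd.Index(order, name="group"), columns=["with_event", "without_event"]
    )
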