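"""Differential-expression filtering and behaviour clustering.

Genes significantly and substantially changed between drug/cell-cycle
conditions are grouped by hierarchical clustering into three behaviours:

(i)   lower under drug irrespective of cell-cycle stage;
(ii)  lower under drug only in non-cycling (G1) cells, restored in cells
      that progressed to G2/M;
(iii) higher under drug irrespective of cell-cycle stage.

Cluster (i) is further split using S-phase-sorted expression into genes
transiently induced during S (``S-induced``) versus genes that stay low
across G1, S and G2 (``persistently-low``), the latter being candidates
for replication-fidelity defects in cells cycling under drug.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

__all__ = ["select_de_genes", "cluster_behaviours", "split_cluster_i"]

BEHAVIOURS = ("i", "ii", "iii")


def select_de_genes(
    matrix: pd.DataFrame,
    calls: pd.DataFrame,
    p_cutoff: float = 0.01,
    fold_threshold: float = 4.0,
    contrasts: list[str] | None = None,
) -> list[str]:
    """Select genes significant in >= 1 contrast and > ``fold_threshold``-fold
    changed in >= 1 contrast (strict inequality; the two conditions may be
    met in different contrasts).

    ``calls`` is a long frame with columns (gene, contrast, p, log2fc)
    holding externally computed significance calls. Returns the selected
    gene ids sorted.
    """
    required = {"gene", "contrast", "p", "log2fc"}
    if not required <= set(calls.columns):
        raise ValueError(f"calls must have columns {sorted(required)}")
    if contrasts is not None:
        missing = set(contrasts) - set(calls["contrast"])
        if missing:
            raise ValueError(f"missing contrast(s): {sorted(missing)}")
        calls = calls[calls["contrast"].isin(contrasts)]
    unknown = set(calls["gene"]) - set(matrix.index)
    if unknown:
        raise ValueError(f"calls contain genes absent from the matrix: {sorted(unknown)[:5]}")
    log2_threshold = np.log2(fold_threshold)
    sig = calls.loc[calls["p"] < p_cutoff, "gene"]
    big = calls.loc[calls["log2fc"].abs() > log2_threshold, "gene"]
    return sorted(set(sig) & set(big))


def _archetype_vectors(design: dict[str, tuple[str, str]], columns) -> np.ndarray:
    """Signature profiles over conditions for behaviours (i), (ii), (iii)."""
    drug = np.array([design[c][0] == "drug" for c in columns])
    g1 = np.array([design[c][1] == "G1" for c in columns])
    arch = np.stack(
        [
            np.where(drug, -1.0, 1.0),            # (i) down in drug everywhere
            np.where(drug & g1, -1.0, 1.0),       # (ii) down in drug G1 only
            np.where(drug, 1.0, -1.0),            # (iii) up in drug
        ]
    )
    return arch


def cluster_behaviours(
    matrix: pd.DataFrame,
    design: dict[str, tuple[str, str]],
    k: int = 3,
) -> pd.DataFrame:
    """Hierarchically cluster gene profiles and label the behaviours.

    Per-gene condition profiles are z-scored, clustered with correlation
    distance and average linkage, and the tree is cut at ``k`` clusters.
    Cluster labels are mapped to behaviours (i)/(ii)/(iii) by maximizing
    the correlation between cluster mean profiles and the behaviour
    signature vectors (one-to-one assignment).

    ``design`` maps each matrix column to ``(treatment, stage)`` with
    treatment in {'untreated', 'drug'} and stage in {'G1', 'G2M'}.
    Returns a frame indexed by gene with columns (label, sublabel).
    """
    if len(matrix) < k:
        raise ValueError(f"need at least k={k} genes, got {len(matrix)}")
    missing = set(matrix.columns) - set(design)
    if missing:
        raise ValueError(f"design missing columns: {sorted(missing)}")
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    degenerate_rows = (sd == 0).ravel()
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd
    with np.errstate(invalid="ignore", divide="ignore"):
        d = pdist(z, metric="correlation")
    if not np.isfinite(d).all():
        log.warning("degenerate (constant) gene profiles; treating as distance 0")
        d = np.nan_to_num(d, nan=0.0)
    lk = linkage(d, method="average")
    raw = fcluster(lk, t=k, criterion="maxclust")
    labels_found = np.unique(raw)
    if len(labels_found) < k:
        log.warning(
            "degenerate clustering: only %d distinct cluster(s) at k=%d",
            len(labels_found),
            k,
        )
    arch = _archetype_vectors(design, matrix.columns)
    arch_z = (arch - arch.mean(axis=1, keepdims=True)) / arch.std(axis=1, keepdims=True)
    # correlation of each cluster mean with each archetype
    score = np.zeros((len(labels_found), len(BEHAVIOURS)))
    for a, lab in enumerate(labels_found):
        m = z[raw == lab].mean(axis=0)
        msd = m.std()
        mz = (m - m.mean()) / (msd if msd > 0 else 1.0)
        score[a] = arch_z @ mz / len(mz)
    rows, cols = linear_sum_assignment(-score)
    mapping = {labels_found[r]: BEHAVIOURS[c] for r, c in zip(rows, cols)}
    # degenerate case: fewer clusters than behaviours — every cluster mapped
    labels = [mapping[r] for r in raw]
    if degenerate_rows.any():
        log.warning("%d gene(s) with constant profiles", int(degenerate_rows.sum()))
    return pd.DataFrame(
        {"label": labels, "sublabel": "none"},
        index=pd.Index(matrix.index, name="gene"),
    )


def split_cluster_i(
    assignment: pd.DataFrame,
    edu_matrix: pd.DataFrame,
    untreated_col: str = "untreated",
    g1_col: str = "drug_G1",
    s_col: str = "drug_EdU",
    recovery_fraction: float = 0.5,
) -> pd.DataFrame:
    """Split cluster (i) genes by S-phase induction.

    For each cluster-(i) gene the expression deficit under drug is
    ``untreated - drug_G1``; the S-phase recovery is the fraction of that
    deficit recovered in drug-treated S-phase (EdU-positive) cells,
    clipped at zero. Genes with recovery >= ``recovery_fraction`` are
    labelled ``S-induced``, the rest ``persistently-low`` (cluster-(i)
    membership already encodes that expression is not restored in
    G2/M-sorted cells). Non-cluster-(i) genes keep sublabel ``none``.
    """
    for col in (untreated_col, g1_col, s_col):
        if col not in edu_matrix.columns:
            raise ValueError(f"edu_matrix lacks required column {col!r}")
    out = assignment.copy()
    ci = out.index[out["label"] == "i"]
    missing = set(ci) - set(edu_matrix.index)
    if missing:
        raise ValueError(f"cluster-(i) genes absent from edu_matrix: {sorted(missing)[:5]}")
    deficit = (
        edu_matrix.loc[ci, untreated_col] - edu_matrix.loc[ci, g1_col]
    ).to_numpy(dtype=float)
    gain = (edu_matrix.loc[ci, s_col] - edu_matrix.loc[ci, g1_col]).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        recovery = np.where(deficit > 0, gain / deficit, 0.0)
    recovery = np.clip(recovery, 0.0, None)
    sub = np.where(recovery >= recovery_fraction, "S-induced", "persistently-low")
    out.loc[ci, "sublabel"] = sub
    return out
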