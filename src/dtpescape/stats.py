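"""Exact and survival statistics for escape/resistance experiments.

Implements the four tests the analyses rest on: a two-sided Fisher exact
test on 2x2 single-cell event tables, the Mantel–Cox log-rank test and a
Cox proportional-hazards model (Efron or Breslow tie handling) for
time-to-resistant-colony cohorts, and the Kruskal–Wallis rank test for
comparing time-to-resistance across cell lines. The Cox report includes
``risk_reduction = 1 - HR``, the headline effect measure for an
intervention that lowers the hazard of resistance.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

log = logging.getLogger(__name__)

__all__ = [
    "fisher_exact_2x2",
    "logrank_test",
    "LogrankResult",
    "cox_ph",
    "CoxResult",
    "kruskal_wallis",
]


# --------------------------------------------------------------------------
# Fisher's exact test
# --------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of counts.

    Uses the probability-ordering two-sided rule: sum the hypergeometric
    probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table. Computed in
    log space for stability.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("table total must be > 0")
    r1, r2, c1 = a + b, c + d, a + c

    def logcomb(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logp = logcomb(r1, k) + logcomb(r2, c1 - k) - logcomb(n, c1)
    log_obs = float(logp[k == a][0])
    # relative tolerance guards against float noise among equal-probability tables
    keep = logp <= log_obs + 1e-7
    p = float(np.exp(logp[keep]).sum())
    return min(p, 1.0)


# --------------------------------------------------------------------------
# Mantel–Cox log-rank test
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LogrankResult:
    statistic: float  # chi-square, 1 df
    p: float
    observed: float  # events in the first group
    expected: float  # expected events in the first group under H0


def logrank_test(times, events, groups) -> LogrankResult:
    """Mantel–Cox log-rank test comparing two survival curves.

    Tied event times are handled with the standard simultaneous-event
    convention (hypergeometric variance at each distinct event time).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(labels)}")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    in1 = groups == labels[0]
    obs = exp = var = 0.0
    for tj in np.unique(times[events == 1]):
        at_risk = times >= tj
        nj = int(at_risk.sum())
        n1j = int((at_risk & in1).sum())
        dj = int(((times == tj) & (events == 1)).sum())
        d1j = int(((times == tj) & (events == 1) & in1).sum())
        obs += d1j
        exp += dj * n1j / nj
        if nj > 1:
            var += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    if var == 0:
        return LogrankResult(statistic=0.0, p=1.0, observed=obs, expected=exp)
    stat = (obs - exp) ** 2 / var
    return LogrankResult(
        statistic=float(stat),
        p=float(chi2_dist.sf(stat, 1)),
        observed=obs,
        expected=exp,
    )


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------

@dataclass
class CoxResult:
    summary: pd.DataFrame  # per covariate: coef, hr, se, ci, p, risk_reduction
    loglik: float
    converged: bool
    separation_suspected: bool
    n: int
    n_events: int
    score_statistic: float  # global score test at beta = 0
    score_p: float


def _cox_quantities(beta, x, times, events, ties):
    """Partial log-likelihood, score and information (Efron or Breslow)."""
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # descending time
    xs, ws, ts, es = x[order], w[order], times[order], events[order]
    # cumulative risk-set sums walking from the largest time down
    cw = np.cumsum(ws)
    cwx = np.cumsum(ws[:, None] * xs, axis=0)
    cwxx = np.cumsum(ws[:, None, None] * xs[:, :, None] * xs[:, None, :], axis=0)
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    event_times = np.unique(ts[es == 1])
    for tj in event_times:
        in_risk = np.searchsorted(-ts, -tj, side="right") - 1  # last idx with t >= tj
        tied = (ts == tj) & (es == 1)
        d = int(tied.sum())
        s_x = xs[tied].sum(axis=0)
        sw_d = ws[tied].sum()
        swx_d = (ws[tied, None] * xs[tied]).sum(axis=0)
        swxx_d = (
            ws[tied, None, None] * xs[tied, :, None] * xs[tied, None, :]
        ).sum(axis=0)
        sw_r = cw[in_risk]
        swx_r = cwx[in_risk]
        swxx_r = cwxx[in_risk]
        ll += float(s_x @ beta)
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            phi = sw_r - frac * sw_d
            num = swx_r - frac * swx_d
            num2 = swxx_r - frac * swxx_d
            ll -= math.log(phi)
            score += s_x / d - num / phi
            info += num2 / phi - np.outer(num, num) / phi**2
    return ll, score, info


def cox_ph(
    times,
    events,
    covariates,
    ties: str = "efron",
    alpha: float = 0.05,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    ``covariates`` is a DataFrame (or 2-D array) of numeric covariates.
    Ties are handled with the Efron correction by default (``'breslow'``
    selectable). Reports per-covariate hazard ratios with Wald
    ``(1 - alpha)`` confidence intervals and p-values, plus
    ``risk_reduction = 1 - HR``. Convergence requires the maximum absolute
    score below ``tol``; monotone likelihoods (complete separation) are
    flagged rather than silently reported.
    """
    if ties not in {"efron", "breslow"}:
        raise ValueError("ties must be 'efron' or 'breslow'")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(covariates, dtype=float))
        if x.shape[0] != len(times):
            x = x.T
        names = [f"x{i}" for i in range(x.shape[1])]
    n, p = x.shape
    n_events = int(events.sum())
    if n_events < p + 1:
        raise ValueError("need more events than covariates")
    # centre covariates for numerical stability (does not change estimates)
    centre = x.mean(axis=0)
    xc = x - centre

    beta = np.zeros(p)
    ll, score0, info0 = _cox_quantities(beta, xc, times, events, ties)
    score_stat = float(score0 @ np.linalg.solve(info0, score0))
    score_p = float(chi2_dist.sf(score_stat, p))

    converged = False
    separation = False
    score, info = score0, info0
    for _ in range(max_iter):
        if np.abs(score).max() < tol:
            converged = True
            break
        step = np.linalg.solve(info, score)
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_quantities(new_beta, xc, times, events, ties)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_quantities(
                new_beta, xc, times, events, ties
            )
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.abs(beta).max() > 20:
            separation = True
            log.warning(
                "cox_ph: coefficient diverging (|beta| > 20); "
                "complete separation (monotone likelihood) suspected"
            )
            break
    else:
        log.warning("cox_ph: Newton-Raphson did not converge in %d iterations", max_iter)
    if np.abs(score).max() < tol:
        converged = True

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = norm.ppf(1 - alpha / 2)
    hr = np.exp(beta)
    with np.errstate(over="ignore"):  # separated fits report infinite CIs
        summary = pd.DataFrame(
            {
                "coef": beta,
                "hr": hr,
                "se": se,
                "ci_low": np.exp(beta - z * se),
                "ci_high": np.exp(beta + z * se),
                "p": 2 * norm.sf(np.abs(beta) / se),
                "risk_reduction": 1.0 - hr,
            },
            index=pd.Index(names, name="covariate"),
        )
    return CoxResult(
        summary=summary,
        loglik=float(ll),
        converged=converged and not separation,
        separation_suspected=separation,
        n=n,
        n_events=n_events,
        score_statistic=score_stat,
        score_p=score_p,
    )


# --------------------------------------------------------------------------
# Kruskal–Wallis
# --------------------------------------------------------------------------

def kruskal_wallis(samples: list) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    ``samples`` is a list of >= 2 groups of observations; every group must
    be non-empty. Returns ``(H, p)`` with ``p`` from chi-square(k - 1).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    all_vals = np.concatenate(arrays)
    n_total = len(all_vals)
    if n_total < 2:
        raise ValueError("need at least 2 observations in total")
    ranks = rankdata(all_vals)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + len(a)]
        h += r.sum() ** 2 / len(a)
        start += len(a)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    if correction == 0:
        log.warning("kruskal_wallis: all observations identical")
        return 0.0, 1.0
    h /= correction
    h = max(h, 0.0)
    p = float(chi2_dist.sf(h, len(arrays) - 1))
    return float(h), p
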