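"""Stochastic simulator of escape from drug-induced G1 arrest.

The model: a drug-tolerant population sits in G1 arrest. Each arrested
cell independently escapes into S phase at a small rate (reduced by a
CDK4/6-inhibitor factor when present) and dies at an ongoing death rate.
An escaped cell traverses S and G2/M with fixed stage durations; each
completed S phase carries a small probability of acquiring a resistance
amplification. Non-resistant cells divide back into arrest (or die at
division); a resistant cell founds a lineage that doubles on its own
clock, unaffected by the CDK4/6 inhibitor, and becomes a visible colony
at a threshold size. Cells in S phase while a nucleoside label (EdU) is
present become permanently labelled; labelled cells arrest before
division and never divide.

Slow sporadic escape offset by death keeps the bulk population static for
weeks, then a single resistant founder produces a rapidly growing colony
— a long stasis ending in a sudden takeover, which is exactly the
observed phenomenology of drug-tolerant persister cultures.

Time units: rates are per cell per **day**; stage durations and the
resistant doubling time are in **hours**; label window times in **days**;
horizons and colony times in **weeks**.
"""
from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EscapeParams",
    "ResistanceOutcome",
    "simulate_culture",
    "cumulative_label_fraction",
    "pulse_label_fraction",
    "simulate_cohort",
]

DAYS_PER_WEEK = 7.0
H = 1.0 / 24.0  # hours -> days


@dataclass(frozen=True)
class EscapeParams:
    """Parameters of the G1-escape / resistance-acquisition model."""

    n0: int = 10_000
    lambda_escape: float = math.log(2) / 11.0  # per cell per day
    t_S: float = 8.0  # hours
    t_G2M: float = 4.0  # hours
    death_rate: float = 0.0  # per arrested cell per day
    p_resist: float = 0.0  # per completed S phase
    p_death_on_cycle: float = 0.0
    resistant_doubling: float = 18.0  # hours
    colony_threshold: int = 50
    cdk46i_factor: float = 1.0
    edu_on: float | None = None  # days
    edu_off: float | None = None  # days
    edu_arrests: bool = True

    def __post_init__(self):
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.lambda_escape < 0 or self.death_rate < 0:
            raise ValueError("rates must be >= 0")
        for p in (self.p_resist, self.p_death_on_cycle):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.t_S <= 0 or self.t_G2M <= 0 or self.resistant_doubling <= 0:
            raise ValueError("stage durations must be > 0")
        if not 0.0 < self.cdk46i_factor <= 1.0:
            raise ValueError("cdk46i_factor must be in (0, 1]")
        if (self.edu_on is None) != (self.edu_off is None):
            raise ValueError("edu_on and edu_off must be given together")
        if self.edu_on is not None and self.edu_off <= self.edu_on:
            raise ValueError("edu_off must be > edu_on")


@dataclass
class ResistanceOutcome:
    """Result of one simulated culture."""

    resistant: bool
    t_colony: float  # weeks; horizon if no colony
    n_escape_events: int
    n_labelled: int
    live_cells: int
    trajectory: pd.DataFrame | None = None
    event_deltas: list[tuple[float, str, int]] = field(default_factory=list)


def _doublings_to_colony(threshold: int) -> int:
    return max(0, math.ceil(math.log2(threshold)))


def simulate_culture(
    params: EscapeParams,
    horizon_weeks: float,
    seed: int | None = None,
    stop_at_first_colony: bool = False,
    record_trajectory: bool = False,
    record_events: bool = False,
) -> ResistanceOutcome:
    """Run one culture to ``horizon_weeks`` (event-driven, exact).

    Escape and death of arrested cells are exponential (Gillespie over the
    arrested pool); S and G2/M are fixed-duration stages handled through a
    scheduled-event queue. Reproducible for a fixed seed. With
    ``stop_at_first_colony`` the run ends once the colony time is decided
    (later resistant founders can only produce later colonies).
    """
    if horizon_weeks <= 0:
        raise ValueError("horizon must be > 0")
    rng = np.random.default_rng(seed)
    horizon = horizon_weeks * DAYS_PER_WEEK
    lam = params.lambda_escape * params.cdk46i_factor
    delta = params.death_rate
    t_S = params.t_S * H
    t_G2M = params.t_G2M * H
    t_double = params.resistant_doubling * H
    k_col = _doublings_to_colony(params.colony_threshold)

    nA = params.n0
    nS = nG2M = nL = nDead = 0
    n_escapes = n_labelled = 0
    founders: list[float] = []
    queue: list[tuple[float, int, str, bool]] = []  # (time, seq, kind, labelled)
    seq = 0
    t = 0.0
    traj_rows = []
    next_day = 0.0
    deltas: list[tuple[float, str, int]] = []

    def labelled_in_s(t_enter: float) -> bool:
        if params.edu_on is None:
            return False
        return t_enter < params.edu_off and t_enter + t_S > params.edu_on

    def lineage_size(now: float, tf: float) -> int:
        if now < tf:
            return 0
        return 2 ** min(int((now - tf) // t_double), k_col)

    def record_day(upto: float):
        nonlocal next_day
        while next_day <= min(upto, horizon):
            n_res = sum(lineage_size(next_day, tf) for tf in founders)
            traj_rows.append(
                (next_day, nA, nS, nG2M, nL, n_res, nDead)
            )
            next_day += 1.0

    while t < horizon:
        rate = nA * (lam + delta)
        dt = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        t_pool = t + dt
        t_queue = queue[0][0] if queue else math.inf
        t_next = min(t_pool, t_queue)
        if t_next > horizon:
            break
        if record_trajectory:
            record_day(t_next)
        t = t_next
        if t_queue <= t_pool:
            _, _, kind, lab = heapq.heappop(queue)
            if kind == "s_done":
                nS -= 1
                if lab and params.edu_arrests:
                    nL += 1  # permanent arrest before division
                    if record_events:
                        deltas.append((t, "label_arrest", 0))
                elif rng.random() < params.p_resist:
                    founders.append(t + t_G2M)
                    nG2M += 1
                    seq += 1
                    heapq.heappush(queue, (t + t_G2M, seq, "found", lab))
                    if record_events:
                        deltas.append((t, "resist_acquired", 0))
                else:
                    seq += 1
                    heapq.heappush(queue, (t + t_G2M, seq, "divide", lab))
                    nG2M += 1
                    if record_events:
                        deltas.append((t, "s_to_g2m", 0))
            elif kind == "found":
                nG2M -= 1  # the cell enters the resistant lineage (size 1)
                if record_events:
                    deltas.append((t, "founded_lineage", 0))
            elif kind == "divide":
                nG2M -= 1
                if rng.random() < params.p_death_on_cycle:
                    nDead += 1
                    if record_events:
                        deltas.append((t, "death_on_cycle", 0))
                else:
                    nA += 2
                    if record_events:
                        deltas.append((t, "division", 1))
        else:
            # pool event: escape or death of an arrested cell
            if rng.random() < (lam / (lam + delta) if lam + delta > 0 else 0.0):
                nA -= 1
                nS += 1
                n_escapes += 1
                lab = labelled_in_s(t)
                if lab:
                    n_labelled += 1
                seq += 1
                heapq.heappush(queue, (t + t_S, seq, "s_done", lab))
                if record_events:
                    deltas.append((t, "escape", 0))
            else:
                nA -= 1
                nDead += 1
                if record_events:
                    deltas.append((t, "death", 0))
        if stop_at_first_colony and founders:
            break

    if record_trajectory:
        record_day(horizon)
    # founders after G2/M completion found a lineage of size 1 that doubles
    # synchronously every t_double; colony at >= colony_threshold cells
    colony_times = [tf + k_col * t_double for tf in founders]
    t_colony_days = min(colony_times) if colony_times else math.inf
    resistant = t_colony_days <= horizon
    n_res_end = sum(lineage_size(horizon, tf) for tf in founders)
    live = nA + nS + nG2M + nL + n_res_end
    trajectory = (
        pd.DataFrame(
            traj_rows,
            columns=["day", "arrested", "s_phase", "g2m", "labelled_arrested",
                     "resistant", "dead"],
        )
        if record_trajectory
        else None
    )
    return ResistanceOutcome(
        resistant=resistant,
        t_colony=(t_colony_days / DAYS_PER_WEEK) if resistant else horizon_weeks,
        n_escape_events=n_escapes,
        n_labelled=n_labelled,
        live_cells=live,
        trajectory=trajectory,
        event_deltas=deltas,
    )


def cumulative_label_fraction(
    params: EscapeParams, t_days: float, seed: int | None = None
) -> tuple[float, float]:
    """Fraction of cells labelled under continuous labelling from time 0.

    Returns ``(analytic, simulated)``. The analytic branch — valid for
    zero death — is ``1 - exp(-lambda_eff * t)``: with permanent arrest on
    labelling, the labelled fraction simply counts cells that have entered
    S phase at least once by ``t``, i.e. escaped arrest.
    """
    if t_days < 0:
        raise ValueError("t must be >= 0")
    lam = params.lambda_escape * params.cdk46i_factor
    analytic = 1.0 - math.exp(-lam * t_days)
    if t_days == 0:
        return analytic, 0.0
    p = replace(params, edu_on=0.0, edu_off=float(t_days), p_resist=0.0)
    out = simulate_culture(p, horizon_weeks=t_days / DAYS_PER_WEEK, seed=seed)
    return analytic, out.n_labelled / params.n0


def pulse_label_fraction(
    params: EscapeParams,
    pulse_start: float,
    pulse_len: float,
    seed: int | None = None,
) -> float:
    """Fraction of live cells labelled by a pulse (start in days, length in
    hours): cells in S phase at any moment of the pulse window.

    In the rare-escape, zero-death limit the expectation follows the
    renewal approximation ``lambda_eff * (pulse_len + t_S)``.
    """
    if pulse_start < 0 or pulse_len <= 0:
        raise ValueError("pulse must have positive length and start >= 0")
    end = pulse_start + pulse_len * H
    p = replace(params, edu_on=float(pulse_start), edu_off=float(end), p_resist=0.0)
    out = simulate_culture(p, horizon_weeks=end / DAYS_PER_WEEK, seed=seed)
    return out.n_labelled / out.live_cells


def simulate_cohort(
    params_by_group: dict[str, EscapeParams],
    n_cultures: int,
    horizon_weeks: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Independent cultures per group; survival-style records.

    Returns a frame (culture_id, group, time_weeks, event) ready for the
    log-rank and proportional-hazards layer.
    """
    from .synthetic import gen_resistance_cohort

    return gen_resistance_cohort(
        params_by_group, n_cultures=n_cultures, max_weeks=horizon_weeks, seed=seed
    )
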