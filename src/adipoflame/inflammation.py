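"""Cytokine signalling, macrophage polarization and inflammation-onset analysis.

Supercritical adipocytes (volume > v_c) secrete pro-inflammatory cytokines —
TNF-alpha, IL-6 and IL-1beta, lumped into a single "pro" pool in arbitrary
units — at a rate proportional to the adipogenesis probability p_a. M1
macrophages add to the same pool (positive feedback); M2 macrophages feed an
"anti" pool. Both pools decay exponentially, a fixed fraction per 8-hour
step:

    pro(t+1) = (1 - decay) * pro(t) + s_adipo * p_a * N_super + s_M1 * M1
    anti(t+1) = (1 - decay) * anti(t) + s_M2 * M2

so a constant source S settles at the geometric fixed point S/decay.

Macrophage polarization is a phenomenological two-parameter saturating
switch (it replaces a gene-regulatory Boolean-network description, whose
wiring is outside this package's scope, while keeping the module boundary so
a network rule could drop in later): a resting M0 cell becomes M1 with
per-step probability

    p = 1/2 (1 + tanh(a * log10(1 + pro) + b))

and, failing that, M2 with the analogous function of the anti pool; M1/M2
revert to M0 at a small constant rate. All macrophages in a given state share
the same transition probability, so the pool is tracked as exact aggregate
counts with binomial transitions — distributionally identical to per-agent
simulation. Counts are conserved (no creation or death here).

Inflammation onset is declared on a daily M1-fraction series when the
fraction stays at or above a threshold for a sustained run of days; onset
times over replicate simulations feed a hand-rolled Kaplan–Meier
product-limit estimator (with censoring at the simulation horizon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .adipose import AdipocytePopulation
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "InflammationParams",
    "CytokineField",
    "MacrophagePool",
    "secrete_cytokines",
    "switch_probability",
    "polarize_macrophages",
    "detect_onset",
    "KMCurve",
    "km_estimator",
]


@dataclass
class InflammationParams:
    """Rates of the cytokine/polarization layer.

    Secretion rates are in arbitrary concentration units per cell per step;
    ``decay_per_step`` is the fractional loss of both cytokine pools per
    8-hour step; (a, b) shape the saturating switch probabilities;
    ``revert_prob`` is the constant per-step M1/M2 -> M0 reversion
    probability; ``macrophages_per_ul`` sets the fixed macrophage pool size
    per microliter of simulated tissue. Onset of inflammation is an M1
    fraction >= ``onset_threshold`` sustained for
    ``onset_persistence_days`` consecutive days.
    """

    s_adipo: float = 1.0
    s_m1: float = 1.0
    s_m2: float = 1.0
    decay_per_step: float = 0.1
    a_pro: float = 1.0
    b_pro: float = -6.0
    a_anti: float = 1.0
    b_anti: float = -6.0
    revert_prob: float = 0.01
    macrophages_per_ul: int = 100
    onset_threshold: float = 0.5
    onset_persistence_days: int = 30

    def __post_init__(self) -> None:
        for name in ("s_adipo", "s_m1", "s_m2"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0.0 < self.decay_per_step < 1.0:
            raise InvalidParameterError("decay_per_step must be in (0, 1)")
        if not 0.0 <= self.revert_prob <= 1.0:
            raise InvalidParameterError("revert_prob must be in [0, 1]")
        if self.macrophages_per_ul < 1:
            raise InvalidParameterError("macrophages_per_ul must be >= 1")
        if not 0.0 < self.onset_threshold < 1.0:
            raise InvalidParameterError("onset_threshold must be in (0, 1)")
        if self.onset_persistence_days < 1:
            raise InvalidParameterError("onset_persistence_days must be >= 1")


@dataclass(frozen=True)
class CytokineField:
    """Lumped pro- and anti-inflammatory cytokine concentrations (a.u.)."""

    pro: float = 0.0
    anti: float = 0.0
    decay_per_step: float = 0.1

    def __post_init__(self) -> None:
        if self.pro < 0 or self.anti < 0:
            raise InvalidInputError("cytokine concentrations must be >= 0")
        if not 0.0 < self.decay_per_step < 1.0:
            raise InvalidParameterError("decay_per_step must be in (0, 1)")


@dataclass(frozen=True)
class MacrophagePool:
    """Aggregate macrophage counts per phenotype."""

    m0: int
    m1: int = 0
    m2: int = 0

    def __post_init__(self) -> None:
        if min(self.m0, self.m1, self.m2) < 0:
            raise InvalidInputError("macrophage counts must be >= 0")

    @property
    def total(self) -> int:
        return self.m0 + self.m1 + self.m2

    @property
    def m1_fraction(self) -> float:
        return self.m1 / self.total if self.total else 0.0


def secrete_cytokines(
    pop: AdipocytePopulation,
    v_c: float,
    p_a: float,
    pool: MacrophagePool,
    field: CytokineField,
    params: InflammationParams,
) -> CytokineField:
    """One step of cytokine kinetics: decay, then sources.

    Supercritical adipocytes secrete into the pro pool at rate
    ``s_adipo * p_a`` each; M1 macrophages add ``s_m1`` each (positive
    feedback); M2 macrophages add ``s_m2`` each to the anti pool.
    """
    n_super = pop.supercritical_count(v_c)
    keep = 1.0 - field.decay_per_step
    pro = keep * field.pro + params.s_adipo * p_a * n_super + params.s_m1 * pool.m1
    anti = keep * field.anti + params.s_m2 * pool.m2
    return CytokineField(pro=pro, anti=anti, decay_per_step=field.decay_per_step)


def switch_probability(concentration: float, a: float, b: float) -> float:
    """Saturating per-step polarization probability,
    ``1/2 (1 + tanh(a * log10(1 + c) + b))`` — in (0, 1), increasing in c,
    tending to 1 as c grows without bound."""
    if concentration < 0:
        raise InvalidInputError("concentration must be >= 0")
    return 0.5 * (1.0 + math.tanh(a * math.log10(1.0 + concentration) + b))


def polarize_macrophages(
    pool: MacrophagePool,
    field: CytokineField,
    params: InflammationParams,
    rng: np.random.Generator,
) -> MacrophagePool:
    """One polarization step.

    Each M0 tries the M1 switch first (probability driven by the pro pool)
    and, failing that, the M2 switch (anti pool); polarized cells revert to
    M0 with a small constant probability. The total count is conserved.
    """
    p1 = switch_probability(field.pro, params.a_pro, params.b_pro)
    p2 = switch_probability(field.anti, params.a_anti, params.b_anti)
    to_m1 = int(rng.binomial(pool.m0, p1))
    to_m2 = int(rng.binomial(pool.m0 - to_m1, p2))
    back_m1 = int(rng.binomial(pool.m1, params.revert_prob))
    back_m2 = int(rng.binomial(pool.m2, params.revert_prob))
    return MacrophagePool(
        m0=pool.m0 - to_m1 - to_m2 + back_m1 + back_m2,
        m1=pool.m1 + to_m1 - back_m1,
        m2=pool.m2 + to_m2 - back_m2,
    )


def detect_onset(
    m1_fraction_daily, threshold: float, persistence_days: int
) -> int | None:
    """First day d such that the M1 fraction is >= threshold on every day of
    [d, d + persistence_days); ``None`` if no full window qualifies
    (censored at the horizon)."""
    series = np.asarray(m1_fraction_daily, dtype=float)
    if series.size == 0:
        raise InvalidInputError("empty trajectory")
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError("threshold must be in (0, 1)")
    if persistence_days < 1:
        raise InvalidInputError("persistence_days must be >= 1")
    meets = series >= threshold
    if series.size < persistence_days:
        return None
    # run length of consecutive qualifying days ending at each index
    run = np.zeros(series.size, dtype=int)
    count = 0
    for i, ok in enumerate(meets):
        count = count + 1 if ok else 0
        run[i] = count
    hits = np.nonzero(run >= persistence_days)[0]
    if hits.size == 0:
        return None
    return int(hits[0] - persistence_days + 1)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve: here "survival" means not yet having
    triggered the inflammation-onset event."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_estimator(durations, events, horizon: float | None = None) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Parameters
    ----------
    durations : array-like
        Non-negative event or censoring times (days).
    events : array-like of bool
        True where the onset occurred at ``durations[i]``, False for
        censored observations.
    horizon : float, optional
        If given, censored durations are clipped to the horizon.

    Returns
    -------
    KMCurve
        Step function starting at (0, 1); survival is non-increasing and
        S(t) = prod_{t_i <= t} (1 - d_i/n_i) over distinct event times.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size != events.size:
        raise InvalidInputError("durations and events must have equal length")
    if durations.size == 0:
        raise InvalidInputError("no observations")
    if np.any(durations < 0):
        raise InvalidInputError("negative times are not allowed")
    if horizon is not None:
        durations = np.where(events, durations, np.minimum(durations, horizon))
    event_times = np.unique(durations[events])
    times = [0.0]
    survival = [1.0]
    n_at_risk = [durations.size]
    s = 1.0
    for t in event_times:
        n_i = int(np.count_nonzero(durations >= t))
        d_i = int(np.count_nonzero(events & (durations == t)))
        s *= 1.0 - d_i / n_i
        times.append(float(t))
        survival.append(s)
        n_at_risk.append(n_i)
    return KMCurve(
        times=np.asarray(times),
        survival=np.asarray(survival),
        n_at_risk=np.asarray(n_at_risk, dtype=int),
    )
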