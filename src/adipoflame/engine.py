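"""Time-stepped orchestration of the adipose–inflammation simulation.

The simulated system is a small, fixed sample of visceral adipose tissue
(``sim_volume`` μL, default 1 μL) advanced in discrete 8-hour steps (three
steps per day). Each step applies, in order:

1. stochastic adipocyte swelling under the day's effective caloric excess,
2. the supercritical fraction zeta and the adipogenesis probability p_a,
3. recruitment of new adipocytes,
4. cytokine secretion and decay,
5. macrophage polarization.

Diet protocols carry a daily excess energy (kcal/day, may be negative) with
a repeating weekly on/off mask (day indices ``day % 7 < days_on_per_week``
are "on" days). Body weight is recorded daily through the fat-mass map
``BW(t) = BW(0) + FM(0)/(1-delta) * (V(t)-V(0))/V(0)``.

Every run is deterministic given its configuration and seed; replicate ``r``
of a replicate set uses seed ``base_seed + r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import anthropometry as anthro
from .adipose import (
    AdipocytePopulation,
    GrowthParams,
    adipogenesis_probability,
    init_population,
    recruit_adipocytes,
    supercritical_fraction,
    update_volumes,
)
from .errors import InvalidInputError
from .inflammation import (
    CytokineField,
    InflammationParams,
    KMCurve,
    MacrophagePool,
    detect_onset,
    km_estimator,
    polarize_macrophages,
    secrete_cytokines,
)

__all__ = [
    "DietProtocol",
    "SimulationConfig",
    "SimulationState",
    "Trajectory",
    "ReplicateSet",
    "SweepResult",
    "step",
    "run",
    "run_replicates",
    "sweep",
]

TRAJECTORY_COLUMNS = [
    "day",
    "bw_kg",
    "n_cells",
    "v_total_ul",
    "mean_volume_ul",
    "zeta",
    "pro",
    "anti",
    "m0",
    "m1",
    "m2",
]


@dataclass(frozen=True)
class DietProtocol:
    """Daily excess energy schedule with a repeating weekly on/off pattern."""

    excess_kcal_per_day: float
    duration_days: int
    days_on_per_week: int = 7

    def __post_init__(self) -> None:
        if not 1 <= self.days_on_per_week <= 7:
            raise InvalidInputError(
                f"days_on_per_week must be in 1..7, got {self.days_on_per_week}"
            )
        if self.duration_days < 0:
            raise InvalidInputError("duration_days must be >= 0")

    def is_on_day(self, day: int) -> bool:
        return day % 7 < self.days_on_per_week

    def effective_excess(self, day: int) -> float:
        """Excess energy applied on ``day`` (0-based); 0 on off days."""
        if day >= self.duration_days:
            return 0.0
        return self.excess_kcal_per_day if self.is_on_day(day) else 0.0

    @property
    def realized_on_days(self) -> int:
        """Number of days in the protocol on which the excess is applied."""
        return sum(self.is_on_day(d) for d in range(self.duration_days))


@dataclass
class SimulationConfig:
    """Complete, serialisable description of one simulation experiment."""

    subject: anthro.SubjectProfile
    protocol: DietProtocol
    growth: GrowthParams | None = None
    inflammation: InflammationParams = field(default_factory=InflammationParams)
    sim_volume: float = 1.0  # μL of simulated adipose tissue
    steps_per_day: int = 3  # 8-hour steps
    replicates: int = 50
    base_seed: int = 1234

    def __post_init__(self) -> None:
        if self.growth is None:
            self.growth = GrowthParams.for_gender(self.subject.gender)
        elif self.growth.v_c is None:
            self.growth = replace(
                self.growth, v_c=anthro.critical_volume(self.subject.gender)
            )
        if not self.sim_volume > 0:
            raise InvalidInputError("sim_volume must be > 0")
        if self.steps_per_day < 1:
            raise InvalidInputError("steps_per_day must be >= 1")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")


@dataclass
class SimulationState:
    """Mutable per-step state of one replicate."""

    population: AdipocytePopulation
    pool: MacrophagePool
    cytokines: CytokineField
    zeta: float = 0.0
    p_a: float = 0.0
    step_index: int = 0


@dataclass
class Trajectory:
    """Daily records of one replicate plus run metadata.

    ``frame`` has one row per simulated day (day 0 is the initial state)
    with columns day, bw_kg, n_cells, v_total_ul, mean_volume_ul, zeta, pro,
    anti, m0, m1, m2.
    """

    frame: pd.DataFrame
    meta: dict

    @property
    def m1_fraction(self) -> np.ndarray:
        f = self.frame
        total = (f["m0"] + f["m1"] + f["m2"]).to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, f["m1"].to_numpy(dtype=float) / total, 0.0)

    def weight_gain(self) -> float:
        return float(self.frame["bw_kg"].iloc[-1] - self.frame["bw_kg"].iloc[0])


@dataclass
class ReplicateSet:
    """A collection of replicate trajectories and their per-day summary."""

    trajectories: list[Trajectory]
    summary: pd.DataFrame  # day + mean/sd for each recorded quantity

    def mean_final_weight(self) -> float:
        return float(self.summary["bw_kg_mean"].iloc[-1])

    def mean_weight_gain(self) -> float:
        s = self.summary["bw_kg_mean"]
        return float(s.iloc[-1] - s.iloc[0])


@dataclass
class SweepResult:
    """Per-excess-energy summaries of a multi-year sweep."""

    e_values: list[float]
    summaries: dict[float, pd.DataFrame]
    year_end_counts: pd.DataFrame  # columns: E_kcal_day, year, m1_mean, m2_mean
    year_end_replicates: pd.DataFrame  # per-replicate year-end M1/M2 counts
    onsets: pd.DataFrame  # columns: replicate, E_kcal_day, onset_day, event_flag
    km_curves: dict[float, KMCurve]


def _initial_state(config: SimulationConfig, rng: np.random.Generator) -> SimulationState:
    population = init_population(config.subject, config.growth, config.sim_volume, rng)
    n_macro = max(1, round(config.inflammation.macrophages_per_ul * config.sim_volume))
    pool = MacrophagePool(m0=n_macro)
    cytokines = CytokineField(decay_per_step=config.inflammation.decay_per_step)
    zeta = supercritical_fraction(population, config.growth.v_c)
    p_a = float(adipogenesis_probability(zeta, config.growth.k5, config.growth.k6))
    return SimulationState(population, pool, cytokines, zeta=zeta, p_a=p_a)


def step(
    state: SimulationState,
    config: SimulationConfig,
    day_excess_kcal: float,
    rng: np.random.Generator,
) -> SimulationState:
    """Advance the state by one 8-hour step under the day's effective excess."""
    g = config.growth
    population = update_volumes(
        state.population,
        day_excess_kcal,
        g,
        config.steps_per_day,
        rng,
        sim_volume=config.sim_volume,
    )
    zeta = supercritical_fraction(population, g.v_c)
    p_a = float(adipogenesis_probability(zeta, g.k5, g.k6))
    population = recruit_adipocytes(population, p_a, config.sim_volume, g, rng)
    cytokines = secrete_cytokines(
        population, g.v_c, p_a, state.pool, state.cytokines, config.inflammation
    )
    pool = polarize_macrophages(state.pool, cytokines, config.inflammation, rng)
    return SimulationState(
        population, pool, cytokines, zeta=zeta, p_a=p_a, step_index=state.step_index + 1
    )


def _record(day: int, state: SimulationState, bw: float) -> tuple:
    pop = state.population
    return (
        day,
        bw,
        pop.n,
        pop.total_volume,
        pop.mean_volume,
        state.zeta,
        state.cytokines.pro,
        state.cytokines.anti,
        state.pool.m0,
        state.pool.m1,
        state.pool.m2,
    )


def run(config: SimulationConfig, seed: int | None = None) -> Trajectory:
    """Simulate one replicate for the protocol's full duration.

    Deterministic given (config, seed); ``seed`` defaults to
    ``config.base_seed``.
    """
    used_seed = config.base_seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    subject = config.subject
    fm0 = anthro.fat_mass(subject)
    delta_ffm = anthro.FFM_PARAMS[subject.gender].delta_ffm
    bw0 = subject.body_weight_0
    state = _initial_state(config, rng)
    v_initial = state.population.total_volume
    records = [_record(0, state, bw0)]
    total_steps = config.protocol.duration_days * config.steps_per_day
    for s in range(total_steps):
        day = s // config.steps_per_day
        excess = config.protocol.effective_excess(day)
        state = step(state, config, excess, rng)
        if (s + 1) % config.steps_per_day == 0:
            bw = anthro.body_weight(
                state.population.total_volume / v_initial, fm0, delta_ffm, bw0
            )
            records.append(_record(day + 1, state, bw))
    frame = pd.DataFrame.from_records(records, columns=TRAJECTORY_COLUMNS)
    meta = {
        "seed": int(used_seed),
        "n0": int(records[0][2]),
        "fm0_kg": fm0,
        "v_initial_ul": v_initial,
        "realized_on_days": config.protocol.realized_on_days,
    }
    return Trajectory(frame=frame, meta=meta)


def run_replicates(config: SimulationConfig) -> ReplicateSet:
    """Run ``config.replicates`` independent replicates (seed base_seed + r)
    and summarise per-day means and standard deviations."""
    trajectories = [run(config, seed=config.base_seed + r) for r in range(config.replicates)]
    value_cols = [c for c in TRAJECTORY_COLUMNS if c != "day"]
    stacked = pd.concat([t.frame for t in trajectories])
    grouped = stacked.groupby("day")[value_cols]
    means = grouped.mean().add_suffix("_mean")
    sds = grouped.std(ddof=0).add_suffix("_sd")
    summary = pd.concat([means, sds], axis=1).reset_index()
    return ReplicateSet(trajectories=trajectories, summary=summary)


def sweep(
    config: SimulationConfig,
    e_values: Sequence[float],
    horizon_years: float,
    replicates: int | None = None,
) -> SweepResult:
    """Run a replicate set per excess-energy value over a multi-year horizon.

    Emits per-day summaries, year-end M1/M2 counts (trailing 30-day means,
    averaged over replicates) and inflammation-onset times per replicate for
    the Kaplan–Meier analysis. The same seed set (base_seed + r) is reused
    for every E so curves are comparable pathwise.
    """
    horizon_days = int(round(horizon_years * 365))
    if horizon_days < 1:
        raise InvalidInputError("horizon must be at least one day")
    n_rep = replicates if replicates is not None else config.replicates
    infl = config.inflammation
    summaries: dict[float, pd.DataFrame] = {}
    km_curves: dict[float, KMCurve] = {}
    year_rows = []
    year_rep_rows = []
    onset_rows = []
    for e in e_values:
        cfg = replace(
            config,
            protocol=DietProtocol(
                excess_kcal_per_day=float(e),
                duration_days=horizon_days,
                days_on_per_week=config.protocol.days_on_per_week,
            ),
            replicates=n_rep,
        )
        reps = run_replicates(cfg)
        summaries[float(e)] = reps.summary
        durations, events = [], []
        for r, traj in enumerate(reps.trajectories):
            onset = detect_onset(
                traj.m1_fraction, infl.onset_threshold, infl.onset_persistence_days
            )
            event = onset is not None
            durations.append(onset if event else horizon_days)
            events.append(event)
            onset_rows.append(
                {
                    "replicate": r,
                    "E_kcal_day": float(e),
                    "onset_day": onset if event else horizon_days,
                    "event_flag": int(event),
                }
            )
        km_curves[float(e)] = km_estimator(durations, events, horizon=horizon_days)
        for year in range(1, int(horizon_days // 365) + 1):
            day_end = year * 365
            m1s, m2s = [], []
            for r, t in enumerate(reps.trajectories):
                # year-end count = trailing 30-day mean (damps polarization noise)
                w = t.frame[(t.frame["day"] > day_end - 30) & (t.frame["day"] <= day_end)]
                m1, m2 = float(w["m1"].mean()), float(w["m2"].mean())
                m1s.append(m1)
                m2s.append(m2)
                year_rep_rows.append(
                    {
                        "E_kcal_day": float(e),
                        "year": year,
                        "replicate": r,
                        "m1": m1,
                        "m2": m2,
                    }
                )
            year_rows.append(
                {
                    "E_kcal_day": float(e),
                    "year": year,
                    "m1_mean": float(np.mean(m1s)),
                    "m2_mean": float(np.mean(m2s)),
                }
            )
    return SweepResult(
        e_values=[float(e) for e in e_values],
        summaries=summaries,
        year_end_counts=pd.DataFrame(year_rows),
        year_end_replicates=pd.DataFrame(year_rep_rows),
        onsets=pd.DataFrame(onset_rows),
        km_curves=km_curves,
    )
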