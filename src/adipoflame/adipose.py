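"""Stochastic adipocyte population dynamics (hypertrophy and hyperplasia).

Each adipocyte is a spherical fat reservoir of volume ``v`` (μL). Under a
daily caloric excess ``E`` (kcal/day) a cell passes a per-step Bernoulli
"swelling" draw with probability

    p_s = 1/2 (1 + tanh(k1*theta + k2)),   theta = 1 - v/v_c,

so small cells almost surely take up lipid while cells beyond the critical
volume ``v_c`` rarely do. A passing cell gains a deterministic lipid-volume
increment plus zero-mean Gaussian noise whose standard deviation is
proportional to the baseline volume, sd = k4*v0; volumes never drop below
``v0`` (the update is rejected instead). Reading k4*v0 as the noise
*variance* instead would make the per-step noise amplitude ~1.6 v0 — larger
than a whole baseline cell — and the floor then rectifies the resulting
volume diffusion into a spurious ~2 kg/year weight gain and a full-blown
inflammatory state at zero caloric excess, so the amplitude reading is used
(see docs/methods.md).

Cells whose volume exceeds ``v_c`` secrete adipogenic growth factors; the
supercritical fraction zeta drives the per-step probability of recruiting new
adipocytes from precursors,

    p_a = 1/2 (tanh(k5*zeta + k6) + tanh 1),

which is exactly 0 at zeta = 0 with the default k6 = -1. On a successful draw
one new cell per microliter of the simulated tissue sample is created at
volume v0 — hyperplasia adds fresh reservoirs for further fat accrual.

Energy partitioning. ``k3*E`` has units of μL/day and is interpreted, per
cell, as the daily lipid-volume uptake of a swelling adipocyte scaled by the
dimensionless calibration factor ``energy_partition_scale`` (calibrated once
against the 42-day Diaz overfeeding study and then held fixed; see
docs/methods.md). An alternative reading in which ``k3*E`` is the influx per
μL of current tissue, split across the cells passing the draw, is available
as ``partition_mode="tissue"``; it compounds (influx grows with the tissue)
and is only meaningful on horizons of a few months.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .anthropometry import (
    DIAMETER_PARAMS,
    SubjectProfile,
    adipocyte_diameter,
    bmi,
    critical_volume,
    sphere_diameter,
    sphere_volume,
)
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "DEFAULT_ENERGY_PARTITION_SCALE",
    "GrowthParams",
    "Adipocyte",
    "AdipocytePopulation",
    "init_population",
    "swelling_factor",
    "swelling_probability",
    "update_volumes",
    "supercritical_fraction",
    "adipogenesis_probability",
    "recruit_adipocytes",
]

#: Dimensionless fraction of the nominal daily lipid flux k3*E taken up by a
#: single swelling adipocyte per day. Calibrated once so that the 42-day
#: Diaz protocol (E = 1506 kcal/day, 36 y male, 1.75 m, 73.7 kg, 50
#: replicates) reproduces the observed 7.6 kg mean gain, then reused
#: unchanged for every other protocol.
DEFAULT_ENERGY_PARTITION_SCALE = 3.5376e-4


@dataclass
class GrowthParams:
    """Parameters of the adipocyte growth/recruitment model.

    k1, k2 shape the swelling probability; k3 (μL·day/kcal) converts caloric
    excess to lipid volume; k4 scales the variance of the per-update volume
    noise (variance = k4*v0); k5, k6 shape the adipogenesis probability.
    ``v_c`` is the gender-specific critical volume (μL); leave it ``None`` to
    fill it from the subject's gender via :meth:`for_gender`.
    """

    k1: float = 4.0
    k2: float = 2.0
    k3: float = 8.0e-6
    k4: float = 2.0e-5
    k5: float = 5.0
    k6: float = -1.0
    v0: float = 8.181e-6
    v_c: float | None = None
    energy_partition_scale: float = DEFAULT_ENERGY_PARTITION_SCALE
    partition_mode: str = "per_cell"
    init_cv_diameter: float = 0.1

    def __post_init__(self) -> None:
        if self.partition_mode not in ("per_cell", "tissue"):
            raise InvalidParameterError(
                f"partition_mode must be 'per_cell' or 'tissue', got {self.partition_mode!r}"
            )
        if not self.v0 > 0:
            raise InvalidParameterError(f"v0 must be > 0, got {self.v0}")
        if self.v_c is not None and not self.v_c > 0:
            raise InvalidParameterError(f"v_c must be > 0, got {self.v_c}")
        if self.k4 < 0:
            raise InvalidParameterError(f"k4 must be >= 0, got {self.k4}")
        if self.energy_partition_scale < 0:
            raise InvalidParameterError("energy_partition_scale must be >= 0")

    @classmethod
    def for_gender(cls, gender: str, **overrides) -> "GrowthParams":
        """Default parameters with v_c set from the gender's critical diameter."""
        params = cls(**overrides)
        if params.v_c is None:
            params = replace(params, v_c=critical_volume(gender))
        return params

    @property
    def noise_sd(self) -> float:
        """Standard deviation (μL) of the per-update volume noise eta,
        proportional to the baseline volume: sd = k4 * v0."""
        return self.k4 * self.v0


@dataclass(frozen=True)
class Adipocyte:
    """A single adipocyte: a convenience view used for inspection, not in the
    vectorised update path."""

    volume: float  # μL
    is_supercritical: bool


@dataclass
class AdipocytePopulation:
    """The simulated adipocyte population.

    Volumes are held in a flat float array (μL); the population is well-mixed
    (no spatial arrangement) and cells never die within the model's scope.
    """

    volumes: np.ndarray
    v0: float

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.size < 1:
            raise InvalidInputError("population must contain at least one cell")

    @property
    def n(self) -> int:
        return int(self.volumes.size)

    @property
    def total_volume(self) -> float:
        """V(t) in μL — always recomputed from the member volumes."""
        return float(self.volumes.sum())

    @property
    def mean_volume(self) -> float:
        return float(self.volumes.mean())

    def supercritical_count(self, v_c: float) -> int:
        return int(np.count_nonzero(self.volumes > v_c))

    def cells(self, v_c: float) -> list[Adipocyte]:
        return [Adipocyte(float(v), bool(v > v_c)) for v in self.volumes]

    def copy(self) -> "AdipocytePopulation":
        return AdipocytePopulation(self.volumes.copy(), self.v0)


def init_population(
    profile: SubjectProfile,
    params: GrowthParams,
    sim_volume: float,
    rng: np.random.Generator,
) -> AdipocytePopulation:
    """Initial adipocyte population filling ``sim_volume`` μL of tissue.

    Diameters are drawn from a truncated normal centred on the BMI-implied
    mean diameter with coefficient of variation ``init_cv_diameter``,
    truncated to [diameter(v0), 2*phi_c], then converted to volumes. The cell
    count is N0 = round(sim_volume / volume(mean diameter)).
    """
    if not sim_volume > 0:
        raise InvalidInputError(f"sim_volume must be > 0, got {sim_volume}")
    d_mean = adipocyte_diameter(bmi(profile), profile.gender)
    mean_cell_volume = sphere_volume(d_mean)
    n0 = max(1, round(sim_volume / mean_cell_volume))
    if n0 < 10:
        warnings.warn(
            f"initial population of {n0} cells is too small for meaningful "
            "statistics; increase sim_volume",
            stacklevel=2,
        )
    d_lo = sphere_diameter(params.v0)
    d_hi = 2.0 * DIAMETER_PARAMS[profile.gender].phi_c
    sd = params.init_cv_diameter * d_mean
    if sd > 0:
        a, b = (d_lo - d_mean) / sd, (d_hi - d_mean) / sd
        diameters = stats.truncnorm.rvs(a, b, loc=d_mean, scale=sd, size=n0, random_state=rng)
    else:
        diameters = np.full(n0, d_mean)
    volumes = (math.pi / 6.0) * diameters**3 / 1.0e9
    # the lower truncation at diameter(v0) already enforces the volume floor
    np.maximum(volumes, params.v0, out=volumes)
    return AdipocytePopulation(volumes, params.v0)


def swelling_factor(v, v_c: float):
    """theta = 1 − v/v_c: positive below the critical volume, 0 at v_c,
    negative above. Accepts scalars or arrays."""
    return 1.0 - np.asarray(v, dtype=float) / v_c


def swelling_probability(theta, k1: float = 4.0, k2: float = 2.0):
    """Per-step probability that a cell takes up lipid,
    ``1/2 (1 + tanh(k1*theta + k2))`` — strictly increasing in theta, hence
    decreasing in the cell volume. Always in (0, 1)."""
    return 0.5 * (1.0 + np.tanh(k1 * np.asarray(theta, dtype=float) + k2))


def adipogenesis_probability(zeta, k5: float = 5.0, k6: float = -1.0):
    """Per-step probability of recruiting new adipocytes,
    ``1/2 (tanh(k5*zeta + k6) + tanh 1)``, clipped to [0, 1].

    With the default k6 = −1 this is exactly 0 at zeta = 0 (oddness of tanh)
    and ≈ 0.88046 at zeta = 1.
    """
    p = 0.5 * (np.tanh(k5 * np.asarray(zeta, dtype=float) + k6) + math.tanh(1.0))
    return np.clip(p, 0.0, 1.0)


def update_volumes(
    pop: AdipocytePopulation,
    excess_kcal_day: float,
    params: GrowthParams,
    steps_per_day: int,
    rng: np.random.Generator,
    sim_volume: float = 1.0,
) -> AdipocytePopulation:
    """Apply one 8-hour swelling step under daily caloric excess ``E``.

    Every cell independently passes a Bernoulli(p_s) draw; each passing cell
    gains the deterministic increment plus zero-mean Gaussian noise of
    standard deviation k4*v0. A cell
    whose updated volume would fall below v0 is left unchanged. The daily
    energy is split uniformly across the ``steps_per_day`` steps.
    """
    if steps_per_day < 1:
        raise InvalidInputError(f"steps_per_day must be >= 1, got {steps_per_day}")
    if params.v_c is None:
        raise InvalidParameterError("params.v_c is unset; use GrowthParams.for_gender")
    v = pop.volumes
    p_s = swelling_probability(swelling_factor(v, params.v_c), params.k1, params.k2)
    passing = rng.random(v.size) < p_s
    n_passing = int(passing.sum())
    new_v = v.copy()
    if n_passing:
        step_energy = excess_kcal_day / steps_per_day
        if params.partition_mode == "per_cell":
            inc = params.energy_partition_scale * params.k3 * step_energy
        else:  # "tissue": daily influx per μL of current tissue, shared by passers
            inc = (
                params.energy_partition_scale
                * params.k3
                * step_energy
                * (pop.total_volume / sim_volume)
                / n_passing
            )
        eta = rng.normal(0.0, params.noise_sd, n_passing) if params.k4 > 0 else 0.0
        candidate = v[passing] + inc + eta
        new_v[passing] = np.where(candidate >= params.v0, candidate, v[passing])
    return AdipocytePopulation(new_v, pop.v0)


def supercritical_fraction(pop: AdipocytePopulation, v_c: float) -> float:
    """zeta: the fraction of cells whose volume exceeds v_c, in [0, 1]."""
    return pop.supercritical_count(v_c) / pop.n


def recruit_adipocytes(
    pop: AdipocytePopulation,
    p_a: float,
    sim_volume: float,
    params: GrowthParams,
    rng: np.random.Generator,
) -> AdipocytePopulation:
    """Hyperplasia: with probability ``p_a``, add one cell per microliter of
    the simulated tissue sample, each initialised at the baseline volume v0.

    The new cells enlarge the total tissue volume — fresh reservoirs for
    further fat accumulation.
    """
    if not 0.0 <= p_a <= 1.0:
        raise InvalidInputError(f"p_a must be in [0, 1], got {p_a}")
    n_new = int(round(sim_volume))
    if n_new > 0 and rng.random() < p_a:
        volumes = np.concatenate([pop.volumes, np.full(n_new, params.v0)])
        return AdipocytePopulation(volumes, pop.v0)
    return pop.copy()
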