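"""Closed-form anthropometric relations.

This module links a subject's anthropometrics (body weight BW in kg, height H
in m, age A in years, gender) to the cellular scale of the simulation and back:

* the mean visceral adipocyte diameter as a saturating function of BMI,
  ``phi(BMI) = phi_c - lambda * exp(-delta_d * BMI)`` — an empirical regression
  estimated on omental adipose tissue and applied here to all visceral
  adipocytes;
* the Westerterp regression for fat-free mass,
  ``FFM = alpha + beta*A + gamma*H + delta_ffm*BW`` (adult regression, used as
  printed), and fat mass ``FM = BW - FFM``;
* the linear map from relative adipose-tissue volume change back to body
  weight, ``BW(t) = BW(0) + FM(0)/(1 - delta_ffm) * (V(t) - V(0))/V(0)``.

Unit conventions: diameters in μm, volumes in μL (1 μL = 1e9 μm³, converted
only at the sphere-volume boundary), masses in kg.

The regression parameter named ``delta`` in the literature appears with two
unrelated meanings (the exponential BMI rate in m²/kg and the dimensionless
BW coefficient of the FFM regression); they are kept apart here as
``delta_d`` and ``delta_ffm``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InfeasibleSubjectError, InvalidInputError, InvalidParameterError

__all__ = [
    "UM3_PER_UL",
    "DiameterParams",
    "FfmParams",
    "SubjectProfile",
    "DIAMETER_PARAMS",
    "FFM_PARAMS",
    "bmi",
    "adipocyte_diameter",
    "sphere_volume",
    "sphere_diameter",
    "free_fat_mass",
    "fat_mass",
    "body_weight",
    "critical_volume",
]

#: μm³ per μL — applied only when converting a diameter to a volume.
UM3_PER_UL = 1.0e9

#: Fat mass below which the subject is rejected as outside the regression's
#: validity range: the weight map multiplies by FM(0), so FM(0) ~ 0 would
#: silently freeze the weight dynamics.
MIN_FAT_MASS_KG = 1.0


def _normalize_gender(gender: str) -> str:
    try:
        g = gender.strip().lower()
    except AttributeError as exc:
        raise InvalidInputError(f"gender must be a string, got {gender!r}") from exc
    if g not in ("male", "female"):
        raise InvalidInputError(f"unknown gender {gender!r}; expected 'male' or 'female'")
    return g


@dataclass(frozen=True)
class DiameterParams:
    """Parameters of the diameter–BMI relation for one gender.

    ``phi_c`` is the asymptotic (critical) diameter in μm, ``lam`` the
    exponential amplitude in μm, ``delta_d`` the BMI rate in m²/kg.
    """

    phi_c: float
    lam: float
    delta_d: float


@dataclass(frozen=True)
class FfmParams:
    """Westerterp fat-free-mass regression coefficients for one gender."""

    alpha: float  # kg
    beta: float  # kg/year
    gamma: float  # kg/m
    delta_ffm: float  # dimensionless, in (0, 1)

    def __post_init__(self) -> None:
        if not 0.0 < self.delta_ffm < 1.0:
            raise InvalidParameterError(
                f"delta_ffm must lie in (0, 1), got {self.delta_ffm}"
            )


DIAMETER_PARAMS: dict[str, DiameterParams] = {
    "male": DiameterParams(phi_c=120.0, lam=74.905, delta_d=0.049),
    "female": DiameterParams(phi_c=123.0, lam=198.445, delta_d=0.061),
}

FFM_PARAMS: dict[str, FfmParams] = {
    "male": FfmParams(alpha=-18.36, beta=-0.105, gamma=34.009, delta_ffm=0.292),
    "female": FfmParams(alpha=-12.47, beta=-0.074, gamma=27.392, delta_ffm=0.218),
}


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometric description of the simulated subject.

    Parameters
    ----------
    body_weight_0 : float
        Initial body weight in kg (> 0).
    height : float
        Height in m (> 0).
    age : float
        Age in years (>= 0).
    gender : str
        ``"male"`` or ``"female"`` (case-insensitive).
    """

    body_weight_0: float
    height: float
    age: float
    gender: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gender", _normalize_gender(self.gender))
        if not self.body_weight_0 > 0:
            raise InvalidInputError(f"body_weight_0 must be > 0, got {self.body_weight_0}")
        if not self.height > 0:
            raise InvalidInputError(f"height must be > 0, got {self.height}")
        if self.age < 0:
            raise InvalidInputError(f"age must be >= 0, got {self.age}")

    @property
    def bmi(self) -> float:
        return bmi(self)


def bmi(profile: SubjectProfile) -> float:
    """Body mass index BW/H² in kg/m²."""
    if not profile.height > 0:
        raise InvalidInputError("height must be > 0")
    return profile.body_weight_0 / profile.height**2


def adipocyte_diameter(bmi_value: float, gender: str) -> float:
    """Mean visceral adipocyte diameter (μm) at a given BMI.

    Strictly increasing in BMI and saturating at the gender-specific critical
    diameter ``phi_c`` (120 μm male, 123 μm female).
    """
    if not bmi_value > 0:
        raise InvalidInputError(f"bmi must be > 0, got {bmi_value}")
    p = DIAMETER_PARAMS[_normalize_gender(gender)]
    return p.phi_c - p.lam * math.exp(-p.delta_d * bmi_value)


def sphere_volume(diameter_um: float) -> float:
    """Volume (μL) of a sphere of the given diameter (μm)."""
    if not diameter_um > 0:
        raise InvalidInputError(f"diameter must be > 0, got {diameter_um}")
    return (math.pi / 6.0) * diameter_um**3 / UM3_PER_UL


def sphere_diameter(volume_ul: float) -> float:
    """Diameter (μm) of a sphere of the given volume (μL). Exact inverse of
    :func:`sphere_volume`."""
    if not volume_ul > 0:
        raise InvalidInputError(f"volume must be > 0, got {volume_ul}")
    return (6.0 * volume_ul * UM3_PER_UL / math.pi) ** (1.0 / 3.0)


def free_fat_mass(profile: SubjectProfile) -> float:
    """Fat-free mass (kg) from the Westerterp adult regression."""
    p = FFM_PARAMS[profile.gender]
    return (
        p.alpha
        + p.beta * profile.age
        + p.gamma * profile.height
        + p.delta_ffm * profile.body_weight_0
    )


def fat_mass(profile: SubjectProfile) -> float:
    """Fat mass FM = BW − FFM (kg).

    Raises
    ------
    InfeasibleSubjectError
        If the regression predicts FM <= 1 kg: such a subject has essentially
        no fat reservoir and lies outside the regression's validity range.
    """
    fm = profile.body_weight_0 - free_fat_mass(profile)
    if fm <= MIN_FAT_MASS_KG:
        raise InfeasibleSubjectError(
            f"predicted fat mass {fm:.2f} kg <= {MIN_FAT_MASS_KG} kg; "
            "subject is outside the validity range of the FFM regression"
        )
    return fm


def body_weight(
    population_volume_ratio: float, fm0: float, delta_ffm: float, bw0: float
) -> float:
    """Body weight (kg) implied by the relative adipose volume V(t)/V(0).

    ``BW(t) = BW(0) + FM(0)/(1 − delta_ffm) · (V(t) − V(0))/V(0)`` — linear in
    the volume ratio and exactly BW(0) at ratio 1.
    """
    if delta_ffm >= 1.0:
        raise InvalidParameterError(f"delta_ffm must be < 1, got {delta_ffm}")
    if not population_volume_ratio > 0:
        raise InvalidInputError(
            f"volume ratio must be > 0, got {population_volume_ratio}"
        )
    return bw0 + fm0 / (1.0 - delta_ffm) * (population_volume_ratio - 1.0)


def critical_volume(gender: str) -> float:
    """Critical adipocyte volume v_c (μL): the spherical volume at phi_c."""
    return sphere_volume(DIAMETER_PARAMS[_normalize_gender(gender)].phi_c)
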