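"""Covariate machinery: derived covariates, scaling laws and the final-model
parameter equations mapping (typical values, covariates, random effects) to
individual two-compartment parameters.

Continuous covariates scale a parameter as ``(value / reference) ** theta``
with the reference fixed at the population median; categorical (0/1)
covariates scale as ``exp(theta * value)``. Inter-individual variability
enters exponentially, ``P_i = P_typ * exp(eta_i)``, so parameters stay
positive and are log-normally distributed across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .structural import PKParameters

__all__ = [
    "CR_UMOL_PER_MGDL",
    "CovariateRecord",
    "ThetaSet",
    "EtaVector",
    "derive_bmi",
    "derive_clcr",
    "covariate_multiplier",
    "individual_parameters",
]

#: serum creatinine unit conversion: 1 mg/dL = 88.4 µmol/L
CR_UMOL_PER_MGDL = 88.4


@dataclass(frozen=True)
class CovariateRecord:
    """Baseline covariates for one subject.

    ``sex``: 0 = male, 1 = female. ``disease``: 0 = healthy, 1 = duodenal
    ulcer. ``serum_creatinine`` is in mg/dL (convert from µmol/L with
    :data:`CR_UMOL_PER_MGDL`). Optional labs: total protein TP (g/L), albumin
    ALB (g/L), platelets PLT (10^9/L), ALT/AST (U/L), total bilirubin TBIL
    (µmol/L).
    """

    sex: int
    disease: int
    age: float
    height: float
    weight: float
    serum_creatinine: float
    TP: Optional[float] = None
    ALB: Optional[float] = None
    PLT: Optional[float] = None
    ALT: Optional[float] = None
    AST: Optional[float] = None
    TBIL: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in (0, 1) or self.disease not in (0, 1):
            raise ValueError("sex and disease must be binary 0/1")
        for name in ("age", "height", "weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ThetaSet:
    """Fixed effects of the final model.

    Defaults are the published final-model estimates: typical values
    tv_V = 6.795 L, tv_Vp = 5.544 L, tv_CL = 3.394 L/h, tv_CLp = 13.086 L/h;
    covariate effects sex→CL −0.213, weight→Vp exponent 1.545,
    disease→CL 0.290, disease→Vp 0.356; reference weight 60.6 kg (the
    analysis-population median).
    """

    tv_V: float = 6.795
    tv_Vp: float = 5.544
    tv_CL: float = 3.394
    tv_CLp: float = 13.086
    theta_sex_CL: float = -0.213
    theta_wt_Vp: float = 1.545
    theta_dis_CL: float = 0.290
    theta_dis_Vp: float = 0.356
    wt_reference: float = 60.6

    def __post_init__(self) -> None:
        for name in ("tv_V", "tv_Vp", "tv_CL", "tv_CLp", "wt_reference"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EtaVector:
    """Subject-level random effects; eta on CLp is structurally fixed to 0
    (no estimated inter-individual variability on CLp)."""

    eta_V: float = 0.0
    eta_Vp: float = 0.0
    eta_CL: float = 0.0

    def __post_init__(self) -> None:
        for name in ("eta_V", "eta_Vp", "eta_CL"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def derive_bmi(weight: float, height: float) -> float:
    """Body-mass index, kg/m², from weight (kg) and height (cm)."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return weight / (height / 100.0) ** 2


def derive_clcr(age: float, weight: float, scr: float, sex: int) -> float:
    """Cockcroft–Gault creatinine clearance, mL/min.

    ``(140 - age) * weight / (72 * scr)``, multiplied by 0.85 for females
    (sex = 1). ``scr`` is serum creatinine in mg/dL.
    """
    if scr <= 0:
        raise ValueError("serum creatinine must be positive (mg/dL)")
    if not 0 <= age <= 140:
        raise ValueError("age must be in [0, 140] years")
    if sex not in (0, 1):
        raise ValueError("sex must be 0 (male) or 1 (female)")
    clcr = (140.0 - age) * weight / (72.0 * scr)
    return clcr * 0.85 if sex == 1 else clcr


def covariate_multiplier(form: str, value: float, reference: float | None = None,
                         theta: float = 0.0) -> float:
    """Multiplicative covariate effect on a structural parameter.

    ``form='continuous'``: power law ``(value/reference)**theta``;
    ``form='categorical'``: ``exp(theta*value)`` for a 0/1 indicator.
    """
    if form == "continuous":
        if reference is None or reference <= 0:
            raise ValueError("continuous form needs a positive reference")
        if value <= 0:
            raise ValueError("continuous covariate value must be positive")
        return float((value / reference) ** theta)
    if form == "categorical":
        return float(np.exp(theta * value))
    raise ValueError(f"unknown covariate form {form!r}")


def individual_parameters(theta: ThetaSet, cov: CovariateRecord,
                          eta: EtaVector = EtaVector()) -> PKParameters:
    """Final-model individual parameters.

    V   = tv_V * exp(eta_V)
    CL  = tv_CL * exp(theta_sex_CL * sex) * exp(theta_dis_CL * disease) * exp(eta_CL)
    Vp  = tv_Vp * (weight / wt_ref)^theta_wt_Vp * exp(theta_dis_Vp * disease) * exp(eta_Vp)
    CLp = tv_CLp   (no covariates, no inter-individual variability)
    """
    V = theta.tv_V * np.exp(eta.eta_V)
    CL = (theta.tv_CL
          * covariate_multiplier("categorical", cov.sex, theta=theta.theta_sex_CL)
          * covariate_multiplier("categorical", cov.disease, theta=theta.theta_dis_CL)
          * np.exp(eta.eta_CL))
    Vp = (theta.tv_Vp
          * covariate_multiplier("continuous", cov.weight, theta.wt_reference,
                                 theta.theta_wt_Vp)
          * covariate_multiplier("categorical", cov.disease, theta=theta.theta_dis_Vp)
          * np.exp(eta.eta_Vp))
    return PKParameters(V=float(V), Vp=float(Vp), CL=float(CL), CLp=theta.tv_CLp)
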