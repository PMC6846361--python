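"""Closed-form estimation of GFR and creatinine clearance from serum creatinine.

Eight serum-creatinine-based models are registered: six GFR models (CamGFR,
Martin, Wright, Mayo quadratic, MDRD-186, CKD-EPI 2009) and two creatinine
clearance models (Cockcroft-Gault, Jelliffe).  Each model's coefficients and
native output scale live in a structured constants file
(``gfrbench/data/model_constants.yaml``) and can be overridden by the user;
formulas here only consume named constants from that registry.

Scales
------
Models natively report either absolute clearance (mL/min) or clearance
normalized to 1.73 m^2 of body surface area (mL/min/1.73 m^2).  Because
measured GFR from nuclear-tracer clearance is an absolute quantity, and
because carboplatin dosing via the Calvert equation consumes absolute GFR,
normalized outputs are converted with ``value * bsa / 1.73``.

All formula kernels are vectorized over numpy arrays; the scalar entry point
is :func:`evaluate_model` and the columnar one :func:`evaluate_frame`.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import yaml

__all__ = [
    "Sex",
    "ModelInput",
    "ModelConstants",
    "GfrEstimate",
    "MODEL_IDS",
    "dubois_bsa",
    "creatinine_to_mgdl",
    "denormalize_gfr",
    "normalize_gfr",
    "calvert_dose",
    "evaluate_model",
    "evaluate_frame",
    "get_constants",
    "registered_models",
    "load_constants",
]

#: micromoles of creatinine per litre equivalent to 1 mg/dL
UMOL_PER_MGDL = 88.42

#: reference body surface area for normalized GFR, m^2
BSA_REF = 1.73

MODEL_IDS = (
    "camgfr",
    "ckd_epi",
    "mdrd186",
    "mayo",
    "wright",
    "martin",
    "cockcroft_gault",
    "jelliffe",
)


class Sex(str, enum.Enum):
    """Patient sex as used by the estimation formulas."""

    MALE = "male"
    FEMALE = "female"


class Scale(str, enum.Enum):
    ABSOLUTE = "absolute_ml_min"
    NORMALIZED = "normalized_ml_min_173"


def dubois_bsa(weight: float, height: float) -> float:
    """Body surface area (m^2) by the DuBois & DuBois equation.

    BSA = 0.007184 * weight^0.425 * height^0.725, weight in kg, height in cm.
    Strictly increasing in both arguments.
    """
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be positive")
    out = 0.007184 * weight**0.425 * height**0.725
    return float(out) if out.ndim == 0 else out


def creatinine_to_mgdl(value: float, unit: str) -> float:
    """Convert a serum creatinine value to mg/dL.

    ``unit`` is ``"mg_dl"`` (identity) or ``"umol_l"`` (divide by 88.42).
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("creatinine must be positive")
    if unit == "mg_dl":
        out = arr
    elif unit == "umol_l":
        out = arr / UMOL_PER_MGDL
    else:
        raise ValueError(f"unknown creatinine unit {unit!r}; use 'mg_dl' or 'umol_l'")
    return float(out) if out.ndim == 0 else out


def denormalize_gfr(value: float, bsa: float) -> float:
    """Convert GFR in mL/min/1.73 m^2 to absolute mL/min for a given BSA."""
    value = np.asarray(value, dtype=float)
    bsa = np.asarray(bsa, dtype=float)
    if np.any(value <= 0) or np.any(bsa <= 0):
        raise ValueError("value and bsa must be positive")
    out = value * bsa / BSA_REF
    return float(out) if out.ndim == 0 else out


def normalize_gfr(value: float, bsa: float) -> float:
    """Convert absolute GFR (mL/min) to mL/min/1.73 m^2 for a given BSA."""
    value = np.asarray(value, dtype=float)
    bsa = np.asarray(bsa, dtype=float)
    if np.any(value <= 0) or np.any(bsa <= 0):
        raise ValueError("value and bsa must be positive")
    out = value * BSA_REF / bsa
    return float(out) if out.ndim == 0 else out


def calvert_dose(target_auc: float, gfr: float) -> float:
    """Carboplatin dose (mg) by the Calvert equation: dose = AUC * (GFR + 25).

    ``target_auc`` in mg*min/mL, ``gfr`` in absolute mL/min.
    """
    if target_auc < 0 or gfr < 0:
        raise ValueError("target_auc and gfr must be non-negative")
    return target_auc * (gfr + 25.0)


# ---------------------------------------------------------------------------
# input / output containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelInput:
    """Covariates consumed by the estimation formulas.

    ``bsa`` is derived from height and weight via DuBois if not supplied.
    Missing race information defaults to nonblack.
    """

    age: float
    sex: Sex
    weight: float
    height: float
    creatinine: float  # mg/dL
    race_black: bool = False
    bsa: float | None = None

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError("age must be >= 18 years")
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")
        if self.creatinine <= 0:
            raise ValueError("creatinine must be positive")
        sex = Sex(self.sex)
        object.__setattr__(self, "sex", sex)
        if self.bsa is None:
            object.__setattr__(self, "bsa", dubois_bsa(self.weight, self.height))
        elif self.bsa <= 0:
            raise ValueError("bsa must be positive")


@dataclass(frozen=True)
class GfrEstimate:
    """One model's estimate for one patient, always carrying absolute mL/min."""

    model_id: str
    value_absolute: float
    value_normalized: float | None
    input_echo: ModelInput


@dataclass(frozen=True)
class ModelConstants:
    """Coefficient set and native output scale of one registered formula."""

    model_id: str
    coefficients: Mapping[str, float]
    native_scale: Scale
    creatinine_unit: str
    source_ref: str


# ---------------------------------------------------------------------------
# formula kernels (vectorized; creatinine always passed in mg/dL)
# ---------------------------------------------------------------------------
# each kernel returns the model's NATIVE-scale value


def _eval_cockcroft_gault(age, female, black, weight, bsa, scr, c):
    return (
        (c["age_offset"] - age)
        * weight
        * np.where(female, c["female_factor"], 1.0)
        / (c["denominator"] * scr)
    )


def _eval_jelliffe(age, female, black, weight, bsa, scr, c):
    return (
        (c["intercept"] - c["age_slope"] * (age - c["age_offset"]))
        * np.where(female, c["female_factor"], 1.0)
        / scr
    )


def _eval_mdrd186(age, female, black, weight, bsa, scr, c):
    return (
        c["scale"]
        * scr ** c["creatinine_exp"]
        * age ** c["age_exp"]
        * np.where(female, c["female_factor"], 1.0)
        * np.where(black, c["black_factor"], 1.0)
    )


def _eval_ckd_epi(age, female, black, weight, bsa, scr, c):
    kappa = np.where(female, c["kappa_female"], c["kappa_male"])
    alpha = np.where(female, c["alpha_female"], c["alpha_male"])
    ratio = scr / kappa
    return (
        c["scale"]
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** c["beta"]
        * c["age_base"] ** age
        * np.where(female, c["female_factor"], 1.0)
        * np.where(black, c["black_factor"], 1.0)
    )


def _eval_mayo(age, female, black, weight, bsa, scr, c):
    # creatinine below the clamp is set to the clamp value (Mayo quadratic rule)
    s = np.maximum(scr, c["creatinine_clamp"])
    return np.exp(
        c["intercept"]
        + c["inv_creatinine"] / s
        + c["inv_creatinine_sq"] / s**2
        + c["age_slope"] * age
        + np.where(female, c["female_term"], 0.0)
    )


def _eval_wright(age, female, black, weight, bsa, scr, c):
    scr_umol = scr * UMOL_PER_MGDL
    return (
        (c["intercept"] - c["age_slope"] * age)
        * bsa
        * (1.0 - c["female_reduction"] * female)
        / scr_umol
    )


def _eval_martin(age, female, black, weight, bsa, scr, c):
    scr_umol = scr * UMOL_PER_MGDL
    return (
        c["scale"]
        * weight
        * (1.0 - c["age_slope"] * age)
        * (1.0 - c["female_reduction"] * female)
        / scr_umol
    )


def _eval_camgfr(age, female, black, weight, bsa, scr, c):
    # square-root-scale linear predictor; absolute-scale output.  The root is
    # floored at a small positive value so the estimate stays positive even at
    # the extreme corner of the admissible domain (very old, very small, very
    # high creatinine), where the linear predictor can cross zero.
    root = (
        c["intercept"]
        + c["age_slope"] * age
        + c["bsa_slope"] * bsa
        + c["log_creatinine_slope"] * np.log(scr)
        + c["creatinine_slope"] * scr
        + np.where(female, c["female_term"], 0.0)
    )
    return np.maximum(root, 0.1) ** 2


_KERNELS: dict[str, Callable] = {
    "cockcroft_gault": _eval_cockcroft_gault,
    "jelliffe": _eval_jelliffe,
    "mdrd186": _eval_mdrd186,
    "ckd_epi": _eval_ckd_epi,
    "mayo": _eval_mayo,
    "wright": _eval_wright,
    "martin": _eval_martin,
    "camgfr": _eval_camgfr,
}


# ---------------------------------------------------------------------------
# constants registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, ModelConstants] | None = None


def load_constants(path: str | None = None) -> dict[str, ModelConstants]:
    """Load the model coefficient table, replacing the active registry.

    By default the packaged ``model_constants.yaml`` is loaded; pass ``path``
    to use an alternative coefficient file of the same layout.
    """
    global _REGISTRY
    if path is None:
        ref = importlib.resources.files("gfrbench").joinpath("data/model_constants.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    registry: dict[str, ModelConstants] = {}
    for model_id, entry in raw["models"].items():
        if model_id not in _KERNELS:
            raise ValueError(f"constants file names unknown model {model_id!r}")
        registry[model_id] = ModelConstants(
            model_id=model_id,
            coefficients=dict(entry["coefficients"]),
            native_scale=Scale(entry["native_scale"]),
            creatinine_unit=entry.get("creatinine_unit", "mg_dl"),
            source_ref=entry["source_ref"],
        )
    _REGISTRY = registry
    return registry


def _registry() -> dict[str, ModelConstants]:
    global _REGISTRY
    if _REGISTRY is None:
        load_constants()
    return _REGISTRY


def get_constants(model_id: str) -> ModelConstants:
    reg = _registry()
    try:
        return reg[model_id]
    except KeyError:
        raise KeyError(
            f"model {model_id!r} is not registered; known models: {sorted(reg)}"
        ) from None


def registered_models() -> tuple[str, ...]:
    return tuple(sorted(_registry()))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _eval_arrays(model_id, age, female, black, weight, bsa, scr):
    const = get_constants(model_id)
    if np.any(scr <= 0):
        raise ValueError("creatinine must be positive")
    native = _KERNELS[model_id](age, female, black, weight, bsa, scr, const.coefficients)
    if const.native_scale is Scale.NORMALIZED:
        absolute = native * bsa / BSA_REF
        normalized = native
    else:
        absolute = native
        normalized = None
    return absolute, normalized


def evaluate_model(model_id: str, inp: ModelInput) -> GfrEstimate:
    """Evaluate one registered model for one patient.

    Returns a :class:`GfrEstimate` with the absolute value (mL/min) always
    populated; the normalized value is present when the model's native scale
    is normalized.  Deterministic (pure) in its inputs.
    """
    absolute, normalized = _eval_arrays(
        model_id,
        np.float64(inp.age),
        np.bool_(inp.sex is Sex.FEMALE),
        np.bool_(inp.race_black),
        np.float64(inp.weight),
        np.float64(inp.bsa),
        np.float64(inp.creatinine),
    )
    return GfrEstimate(
        model_id=model_id,
        value_absolute=float(absolute),
        value_normalized=None if normalized is None else float(normalized),
        input_echo=inp,
    )


def evaluate_frame(model_id: str, frame) -> np.ndarray:
    """Vectorized absolute eGFR (mL/min) for a cohort record frame.

    ``frame`` must carry columns ``age``, ``sex``, ``race_black``,
    ``weight_kg``, ``height_cm``, ``creatinine_mgdl``.
    """
    age = frame["age"].to_numpy(dtype=float)
    female = (frame["sex"].to_numpy() == Sex.FEMALE.value)
    black = frame["race_black"].to_numpy(dtype=bool)
    weight = frame["weight_kg"].to_numpy(dtype=float)
    height = frame["height_cm"].to_numpy(dtype=float)
    bsa = dubois_bsa(weight, height)
    scr = frame["creatinine_mgdl"].to_numpy(dtype=float)
    absolute, _ = _eval_arrays(model_id, age, female, black, weight, bsa, scr)
    return np.asarray(absolute, dtype=float)
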