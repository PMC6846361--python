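"""Synthetic multicenter cohort generator.

Emulates the structure of a seven-center GFR-model validation cohort:
3786 patients split by center, diagnosis group (solid cancer, hematological
cancer, noncancer), sex and race, with continuous marginals calibrated to
the study's summary tables (measured GFR mean 86, SD 32, range 9-209 mL/min;
median creatinine 0.95 mg/dL; median age 60 y; median height 169 cm; median
weight 74 kg; median BSA 1.85 m^2).

Generation is truth-first: a latent true GFR is drawn from a truncated
normal, and the noiseless serum creatinine consistent with that GFR and the
patient's demographics is obtained by numerically inverting the monotone
creatinine -> eGFR map of a configurable truth model.  Multiplicative
lognormal creatinine noise, a global assay calibration factor (non-IDMS
creatinine reads systematically high relative to the IDMS standard), and
per-center calibration factors emulating intercenter assay variability are
then applied, and the measured GFR gets independent additive normal noise.
This construction guarantees the closed-loop identity: with zero noise and
unit calibration the truth model's eGFR equals the recorded mGFR exactly.

The published per-center margins only constrain center x diagnosis counts
plus female and black totals per center; the full center x diagnosis x sex x
race strata table is completed deterministically by largest-remainder
apportionment, so every published margin is reproduced exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import models as _models
from .cohort import Cohort, FilterLogEntry

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "default_strata",
    "scaled_strata",
    "default_config",
    "generate_cohort",
    "inject_center_bias",
    "config_to_yaml",
    "config_from_yaml",
]

# per-center margins: total by diagnosis group, female count, black count.
# tracer assignment: Tc-99m-DTPA in Edinburgh and Melbourne, Cr-51-EDTA elsewhere.
CENTER_MARGINS = {
    # center: (solid, hematological, noncancer, female, black)
    "Cambridge": (227, 114, 63, 198, 6),
    "Edinburgh": (472, 22, 103, 245, 0),
    "London-Barts": (108, 0, 0, 0, 0),
    "Manchester": (1777, 0, 0, 1066, 16),
    "Melbourne": (308, 0, 0, 111, 0),
    "Southampton": (436, 0, 0, 0, 0),
    "Wales": (156, 0, 0, 89, 0),
}

CENTER_TRACER = {
    "Cambridge": "cr51_edta",
    "Edinburgh": "tc99m_dtpa",
    "London-Barts": "cr51_edta",
    "Manchester": "cr51_edta",
    "Melbourne": "tc99m_dtpa",
    "Southampton": "cr51_edta",
    "Wales": "cr51_edta",
}

DIAGNOSES = ("solid_cancer", "hematological_cancer", "noncancer")


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion ``total`` across cells proportionally to ``weights``.

    Deterministic Hamilton method: floor the quotas, then hand remaining
    units to the largest fractional parts (ties -> lowest cell index).
    """
    weights = np.asarray(weights, float)
    if total == 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=int)
    quotas = total * weights / weights.sum()
    out = np.floor(quotas).astype(int)
    frac = quotas - out
    short = total - out.sum()
    order = np.lexsort((np.arange(len(frac)), -frac))
    out[order[:short]] += 1
    return out


def default_strata() -> pd.DataFrame:
    """Full center x diagnosis x sex x race strata table (count column).

    Completed from the per-center margins by largest-remainder
    apportionment: female counts are spread across diagnosis cells in
    proportion to their sizes, then black counts across the resulting
    (diagnosis, sex) cells.  All published margins reproduce exactly and the
    grand total is 3786.
    """
    rows = []
    for center, (solid, heme, nonc, female, black) in CENTER_MARGINS.items():
        diag_counts = np.array([solid, heme, nonc])
        fem_by_diag = _largest_remainder(female, diag_counts)
        # cells ordered (diag0 F, diag0 M, diag1 F, diag1 M, ...)
        cells = []
        for d, diag in enumerate(DIAGNOSES):
            cells.append((diag, "female", fem_by_diag[d]))
            cells.append((diag, "male", diag_counts[d] - fem_by_diag[d]))
        cell_counts = np.array([c[2] for c in cells])
        black_by_cell = _largest_remainder(black, cell_counts)
        for (diag, sex, n), nb in zip(cells, black_by_cell):
            if n - nb > 0:
                rows.append((center, diag, sex, False, int(n - nb)))
            if nb > 0:
                rows.append((center, diag, sex, True, int(nb)))
    return pd.DataFrame(rows, columns=["center", "diagnosis_group", "sex", "race_black", "count"])


def scaled_strata(total: int, strata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rescale a strata table to ``total`` records, preserving proportions.

    Uses the same largest-remainder apportionment as the default table, so
    the result is deterministic and sums exactly to ``total``.
    """
    base = default_strata() if strata is None else strata
    out = base.copy()
    out["count"] = _largest_remainder(total, base["count"].to_numpy())
    return out


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the generator needs; defaults reproduce the study tables.

    Continuous marginals are truncated normals.  ``assay_factor`` is a global
    multiplicative creatinine calibration (non-IDMS assays read high relative
    to IDMS); ``center_calibration`` adds per-center multiplicative factors on
    top of it.  Both default to values that keep the cohort median creatinine
    at the printed 0.95 mg/dL under the default ckd_epi truth model.
    """

    strata_counts: pd.DataFrame = field(default_factory=default_strata)
    # age: truncated normal in years
    age_mean: float = 57.0
    age_sd: float = 16.0
    age_bounds: tuple[float, float] = (18.0, 91.0)
    # height (cm) and weight (kg): per-sex truncated normals coupled through a
    # shared per-person size factor (height-weight correlation ~ sqrt(rho_h*rho_w))
    height_mean: dict = field(default_factory=lambda: {"male": 175.5, "female": 161.5})
    height_sd: dict = field(default_factory=lambda: {"male": 7.5, "female": 7.0})
    height_bounds: tuple[float, float] = (137.0, 204.0)
    weight_mean: dict = field(default_factory=lambda: {"male": 80.0, "female": 68.0})
    weight_sd: dict = field(default_factory=lambda: {"male": 17.0, "female": 15.0})
    weight_bounds: tuple[float, float] = (33.0, 200.0)
    size_correlation: float = 0.5
    # latent true GFR, absolute mL/min.  The latent scale is set so that the
    # REALIZED mGFR marginal (after bound truncation and the feasibility
    # redraw, which clips unattainably high GFR for elderly/small patients)
    # has SD ~= 32 mL/min, the cohort-table value.
    gfr_mean: float = 86.0
    gfr_sd: float = 36.0
    mgfr_bounds: tuple[float, float] = (9.0, 209.0)
    # truth model and measurement model
    truth_model: str = "ckd_epi"
    creatinine_noise_sd: float = 0.06  # lognormal sigma (multiplicative)
    mgfr_noise_sd: float = 5.0  # additive normal SD, mL/min
    assay_factor: float = 1.0  # global creatinine calibration (set by default_config)
    center_calibration: dict = field(default_factory=dict)  # center -> factor
    creatinine_bounds: tuple[float, float] = (0.20, 4.5)
    # dates
    study_start: str = "2013-01-01"
    study_days: int = 1826
    same_day_fraction: float = 0.27
    max_offset_days: int = 30
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self):
        if (self.strata_counts["count"] < 0).any():
            raise ValueError("strata counts must be non-negative")
        if self.assay_factor <= 0 or any(v <= 0 for v in self.center_calibration.values()):
            raise ValueError("calibration factors must be positive")
        if self.creatinine_noise_sd < 0 or self.mgfr_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for lo, hi in (self.age_bounds, self.mgfr_bounds, self.creatinine_bounds,
                       self.height_bounds, self.weight_bounds):
            if not lo < hi:
                raise ValueError("bounds must be ordered")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


#: global assay factor calibrated once (design time) so that the default
#: configuration's cohort median creatinine lands on 0.95 mg/dL
DEFAULT_ASSAY_FACTOR = 1.010


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The packaged default configuration (study-table calibration)."""
    kw = dict(assay_factor=DEFAULT_ASSAY_FACTOR, seed=seed)
    kw.update(overrides)
    return GeneratorConfig(**kw)


@dataclass(frozen=True)
class SyntheticCohort:
    cohort: Cohort
    truth: np.ndarray  # latent true GFR per record, mL/min
    config_echo: GeneratorConfig


def _trunc_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _correlated_trunc(rng, z, mean, sd, lo, hi, rho, max_retries):
    """Per-record truncated normal sharing latent factor ``z`` (weight rho)."""
    n = z.size
    x = mean + sd * (np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.standard_normal(n))
    for _ in range(max_retries):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = mean[bad] + sd[bad] * (
            np.sqrt(rho) * z[bad] + np.sqrt(1 - rho) * rng.standard_normal(bad.sum())
        )
    return np.clip(x, lo, hi)


def _egfr_absolute(model_id, age, female, black, weight, bsa, scr):
    absolute, _ = _models._eval_arrays(model_id, age, female, black, weight, bsa, scr)
    return np.asarray(absolute, float)


def _invert_truth(model_id, age, female, black, weight, bsa, target, bounds, iters=80):
    """Vectorized bisection of the monotone-decreasing creatinine->eGFR map.

    Returns (creatinine, feasible): rows whose target lies outside the range
    attainable on the creatinine bounds are flagged infeasible.
    """
    lo = np.full(target.shape, bounds[0])
    hi = np.full(target.shape, bounds[1])
    f_lo = _egfr_absolute(model_id, age, female, black, weight, bsa, lo)
    f_hi = _egfr_absolute(model_id, age, female, black, weight, bsa, hi)
    feasible = (f_lo >= target) & (target >= f_hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        f_mid = _egfr_absolute(model_id, age, female, black, weight, bsa, mid)
        take_hi = f_mid >= target  # decreasing: eGFR still too high -> move lo up
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    return 0.5 * (lo + hi), feasible


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Draw one synthetic cohort; deterministic given ``config.seed``.

    Per stratum the generator draws demographics, a latent true GFR, the
    truth-consistent noiseless creatinine (numeric inversion), then applies
    creatinine noise and calibration factors and the additive mGFR noise.
    Records that cannot be inverted (true GFR unattainable within the
    creatinine bounds for the drawn demographics) have their true GFR
    redrawn, up to ``config.max_retries`` rounds.
    """
    cfg = config if config is not None else default_config()
    strata = cfg.strata_counts
    n = int(strata["count"].sum())

    ss = np.random.SeedSequence(cfg.seed)
    rng_demo, rng_gfr, rng_noise, rng_dates = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    center = np.repeat(strata["center"].to_numpy(), strata["count"].to_numpy())
    diagnosis = np.repeat(strata["diagnosis_group"].to_numpy(), strata["count"].to_numpy())
    sex = np.repeat(strata["sex"].to_numpy(), strata["count"].to_numpy())
    race = np.repeat(strata["race_black"].to_numpy(dtype=bool), strata["count"].to_numpy())
    female = sex == "female"

    age = _trunc_normal(rng_demo, cfg.age_mean, cfg.age_sd, *cfg.age_bounds, size=n)
    z = rng_demo.standard_normal(n)  # shared size factor
    h_mean = np.where(female, cfg.height_mean["female"], cfg.height_mean["male"])
    h_sd = np.where(female, cfg.height_sd["female"], cfg.height_sd["male"])
    w_mean = np.where(female, cfg.weight_mean["female"], cfg.weight_mean["male"])
    w_sd = np.where(female, cfg.weight_sd["female"], cfg.weight_sd["male"])
    height = _correlated_trunc(rng_demo, z, h_mean, h_sd, *cfg.height_bounds,
                               rho=cfg.size_correlation, max_retries=cfg.max_retries)
    weight = _correlated_trunc(rng_demo, z, w_mean, w_sd, *cfg.weight_bounds,
                               rho=cfg.size_correlation, max_retries=cfg.max_retries)
    bsa = _models.dubois_bsa(weight, height)

    # latent true GFR, redrawing rows whose value cannot be reached by the
    # truth model within the creatinine bounds
    true_gfr = _trunc_normal(rng_gfr, cfg.gfr_mean, cfg.gfr_sd, *cfg.mgfr_bounds, size=n)
    scr_clean, feasible = _invert_truth(
        cfg.truth_model, age, female, race, weight, bsa, true_gfr, cfg.creatinine_bounds
    )
    tries = 0
    while not feasible.all():
        tries += 1
        if tries > cfg.max_retries:
            raise RuntimeError(
                f"truth-model inversion failed for {(~feasible).sum()} records "
                f"after {cfg.max_retries} redraws"
            )
        bad = ~feasible
        true_gfr[bad] = _trunc_normal(
            rng_gfr, cfg.gfr_mean, cfg.gfr_sd, *cfg.mgfr_bounds, size=int(bad.sum())
        )
        scr_bad, ok_bad = _invert_truth(
            cfg.truth_model, age[bad], female[bad], race[bad], weight[bad], bsa[bad],
            true_gfr[bad], cfg.creatinine_bounds,
        )
        scr_clean[bad] = scr_bad
        feasible[bad] = ok_bad

    # measurement model for creatinine: lognormal noise, then calibration
    factor = np.full(n, cfg.assay_factor)
    for c, f in cfg.center_calibration.items():
        factor[center == c] *= f
    lo, hi = cfg.creatinine_bounds
    scr = scr_clean.copy()
    if cfg.creatinine_noise_sd > 0:
        noise = np.exp(rng_noise.normal(0.0, cfg.creatinine_noise_sd, n))
        scr = scr_clean * noise * factor
        for _ in range(cfg.max_retries):
            bad = (scr < lo) | (scr > hi)
            if not bad.any():
                break
            scr[bad] = scr_clean[bad] * np.exp(
                rng_noise.normal(0.0, cfg.creatinine_noise_sd, int(bad.sum()))
            ) * factor[bad]
        scr = np.clip(scr, lo, hi)
    else:
        scr = np.clip(scr_clean * factor, lo, hi)

    # measured GFR: additive tracer-clearance noise, kept within bounds
    glo, ghi = cfg.mgfr_bounds
    mgfr = true_gfr.copy()
    if cfg.mgfr_noise_sd > 0:
        mgfr = true_gfr + rng_noise.normal(0.0, cfg.mgfr_noise_sd, n)
        for _ in range(cfg.max_retries):
            bad = (mgfr < glo) | (mgfr > ghi)
            if not bad.any():
                break
            mgfr[bad] = true_gfr[bad] + rng_noise.normal(0.0, cfg.mgfr_noise_sd, int(bad.sum()))
        mgfr = np.clip(mgfr, glo, ghi)

    # dates: mGFR date uniform over the study window; creatinine same-day with
    # the configured probability, otherwise uniform within +/- max_offset_days
    start = pd.Timestamp(cfg.study_start)
    mgfr_day = rng_dates.integers(0, cfg.study_days, n)
    same_day = rng_dates.random(n) < cfg.same_day_fraction
    offset = rng_dates.integers(-cfg.max_offset_days, cfg.max_offset_days + 1, n)
    offset = np.where(same_day, 0, offset)
    mgfr_date = start + pd.to_timedelta(mgfr_day, unit="D")
    creat_date = mgfr_date + pd.to_timedelta(offset, unit="D")

    records = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(1, n + 1)],
            "center": center,
            "diagnosis_group": diagnosis,
            "sex": sex,
            "race_black": race,
            "age": age,
            "height_cm": height,
            "weight_kg": weight,
            "creatinine_mgdl": scr,
            "creatinine_date": creat_date,
            "mgfr_ml_min": mgfr,
            "tracer": [CENTER_TRACER.get(c, "cr51_edta") for c in center],
            "mgfr_date": mgfr_date,
        }
    )
    cohort = Cohort(records=records, provenance=f"synthetic(seed={cfg.seed})")
    return SyntheticCohort(cohort=cohort, truth=true_gfr, config_echo=cfg)


def inject_center_bias(cohort: Cohort, center_calibration: dict[str, float]) -> Cohort:
    """Multiply each listed center's creatinine by its calibration factor.

    Emulates intercenter creatinine assay variability.  Centers named in the
    map must exist in the cohort; everything except creatinine is untouched.
    """
    if any(f <= 0 for f in center_calibration.values()):
        raise ValueError("calibration factors must be positive")
    df = cohort.records.copy()
    present = set(df["center"].unique())
    unknown = set(center_calibration) - present
    if unknown:
        raise KeyError(f"centers not present in cohort: {sorted(unknown)}")
    for c, f in center_calibration.items():
        df.loc[df["center"] == c, "creatinine_mgdl"] *= f
    return cohort.with_records(df, [FilterLogEntry("inject_center_bias", 0)])


# ---------------------------------------------------------------------------
# config (de)serialization
# ---------------------------------------------------------------------------


def config_to_yaml(cfg: GeneratorConfig, path) -> None:
    d = dataclasses.asdict(cfg)
    d["strata_counts"] = cfg.strata_counts.to_dict(orient="records")
    for key in ("age_bounds", "mgfr_bounds", "creatinine_bounds", "height_bounds", "weight_bounds"):
        d[key] = list(d[key])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "strata_counts" in d and d["strata_counts"] is not None:
        d["strata_counts"] = pd.DataFrame(d["strata_counts"])
    else:
        d.pop("strata_counts", None)
    for key in ("age_bounds", "mgfr_bounds", "creatinine_bounds", "height_bounds", "weight_bounds"):
        if key in d:
            d[key] = tuple(d[key])
    try:
        return GeneratorConfig(**d)
    except TypeError as exc:
        raise ValueError(f"invalid generator config: {exc}") from None
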