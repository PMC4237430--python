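"""Synthetic data: CT-like lobe-labeled phantoms and simulated cohorts.

The phantom generator builds a voxel grid with five disjoint ellipsoidal
lobe regions (LUL/LLL on the left, RUL/RML/RLL on the right, upper lobes
superior to lower ones) filled with Gaussian parenchyma attenuation, and
inserts low-attenuation disc clusters until each lobe reaches a requested
emphysema fraction.  Parenchyma values are truncated above the −950 HU
threshold and cluster values below it, so the target fraction is exact at
the voxel level up to cluster discretisation.

The cohort generator draws demographics, smoking history, emphysema
extent (LAA%) and heterogeneity (HI%) from group-specific distributions
(COPD vs non-COPD) and then produces the pulmonary-function outcomes from
known linear models — and GOLD severity from a known logistic model — so
that the downstream fitting code can be validated by parameter recovery.

All randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .laa import LOBE_NAMES, LabeledVolume

# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------


class PhantomInfeasibleError(ValueError):
    """A lobe's requested emphysema fraction cannot be realised."""


@dataclass
class PhantomSpec:
    """Parameters of a synthetic lobe-labeled CT volume.

    Spacing defaults (0.7 × 0.7 mm in-plane, 0.625 mm sections) sit in the
    thin-section acquisition range typical of COPD imaging protocols.
    ``lobe_laa_fractions`` maps lobe names (LUL, LLL, RUL, RML, RLL) to
    target emphysema fractions in [0, 1].
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (0.7, 0.7, 0.625)
    lobe_laa_fractions: dict[str, float] = field(
        default_factory=lambda: {n: 0.0 for n in LOBE_NAMES.values()}
    )
    parenchyma_hu: tuple[float, float] = (-850.0, 40.0)  # mean, SD
    emphysema_hu: tuple[float, float] = (-980.0, 10.0)
    cluster_radius_mm: tuple[float, float] = (1.0, 8.0)  # log-uniform range
    cluster_slices: tuple[int, int] = (1, 3)
    background_hu: tuple[float, float] = (40.0, 20.0)  # soft tissue
    threshold_hu: float = -950.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if any(d < 8 for d in self.shape):
            raise ValueError("grid too small for five lobes")
        for name, f in self.lobe_laa_fractions.items():
            if name not in LOBE_NAMES.values():
                raise ValueError(f"unknown lobe {name!r}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"lobe {name}: fraction {f} outside [0, 1]")
        if self.cluster_radius_mm[0] <= 0:
            raise ValueError("cluster radii must be positive")


# Normalised ellipsoid geometry: (center, semi-axes) per lobe, in fractions
# of the grid.  Axis 2 is superior-inferior; larger index = more superior.
_LOBE_GEOMETRY = {
    "LUL": ((0.27, 0.50, 0.72), (0.17, 0.34, 0.24)),
    "LLL": ((0.27, 0.50, 0.27), (0.17, 0.34, 0.22)),
    "RUL": ((0.73, 0.46, 0.76), (0.17, 0.32, 0.20)),
    "RML": ((0.74, 0.28, 0.52), (0.14, 0.18, 0.13)),
    "RLL": ((0.73, 0.56, 0.26), (0.17, 0.32, 0.21)),
}
_LOBE_BY_NAME = {v: k for k, v in LOBE_NAMES.items()}


def _lobe_labels(shape: tuple[int, int, int]) -> np.ndarray:
    """Assign each voxel to the nearest containing lobe ellipsoid (0 outside)."""
    grids = np.meshgrid(*[np.arange(d) / (d - 1) for d in shape], indexing="ij")
    labels = np.zeros(shape, dtype=np.int16)
    best = np.full(shape, np.inf)
    for name, (center, axes) in _LOBE_GEOMETRY.items():
        d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
        inside = (d2 <= 1.0) & (d2 < best)
        labels[inside] = _LOBE_BY_NAME[name]
        best = np.where(inside, d2, best)
    return labels


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float,
    high: float,
    size: int,
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Build a lobe-labeled HU volume with controlled per-lobe emphysema.

    Clusters are in-plane discs spanning 1–3 consecutive slices with
    log-uniform radii; insertion continues until each lobe's thresholded
    voxel fraction reaches its target (within ±20% relative).  The same
    seed reproduces the volume bit-for-bit.

    Raises
    ------
    PhantomInfeasibleError
        If a lobe's target cannot be reached (named in the message).
    """
    rng = np.random.default_rng(spec.seed)
    labels = _lobe_labels(spec.shape)
    image = np.empty(spec.shape, dtype=np.float32)

    bg = labels == 0
    image[bg] = rng.normal(*spec.background_hu, size=int(bg.sum()))

    thr = spec.threshold_hu
    p_mean, p_sd = spec.parenchyma_hu
    e_mean, e_sd = spec.emphysema_hu
    lung = ~bg
    # parenchyma strictly above threshold, emphysema strictly below
    image[lung] = _truncated_normal(
        rng, p_mean, p_sd, thr + 1e-3, np.inf, int(lung.sum())
    )

    pixel_area = spec.spacing[0] * spec.spacing[1]
    r_lo, r_hi = spec.cluster_radius_mm
    ii, jj = np.meshgrid(
        np.arange(spec.shape[0]), np.arange(spec.shape[1]), indexing="ij"
    )

    for name, target in spec.lobe_laa_fractions.items():
        if target == 0.0:
            continue
        lbl = _LOBE_BY_NAME[name]
        lobe = labels == lbl
        n_lobe = int(lobe.sum())
        if n_lobe == 0:
            raise PhantomInfeasibleError(f"lobe {name} has no voxels at this grid size")
        target_vox = int(round(target * n_lobe))
        if target_vox > n_lobe:
            raise PhantomInfeasibleError(
                f"lobe {name}: target fraction {target} exceeds lobe capacity"
            )
        emph = np.zeros(spec.shape, dtype=bool)
        count = 0
        coords = np.argwhere(lobe)
        attempts = 0
        while count < target_vox:
            attempts += 1
            if attempts > 50 * max(1, target_vox):
                raise PhantomInfeasibleError(
                    f"lobe {name}: could not reach fraction {target} "
                    f"(achieved {count / n_lobe:.4f})"
                )
            deficit = target_vox - count
            if deficit < 8:
                # finish off with single voxels to avoid overshoot
                free = np.argwhere(lobe & ~emph)
                pick = free[rng.choice(len(free), size=deficit, replace=False)]
                emph[tuple(pick.T)] = True
                count = target_vox
                break
            r_mm = math.exp(rng.uniform(math.log(r_lo), math.log(r_hi)))
            n_slices = int(rng.integers(spec.cluster_slices[0], spec.cluster_slices[1] + 1))
            # cap the cluster so a single insertion cannot overshoot the target
            if math.pi * r_mm**2 / pixel_area * n_slices > deficit:
                n_slices = 1
                r_mm = min(r_mm, math.sqrt(deficit * pixel_area / math.pi))
            ci, cj, ck = coords[rng.integers(len(coords))]
            disc = ((ii - ci) * spec.spacing[0]) ** 2 + (
                (jj - cj) * spec.spacing[1]
            ) ** 2 <= r_mm**2
            for k in range(ck, min(ck + n_slices, spec.shape[2])):
                new = disc & lobe[:, :, k] & ~emph[:, :, k]
                emph[:, :, k] |= new
                count += int(new.sum())
        idx = np.where(emph)
        image[idx] = _truncated_normal(
            rng, e_mean, e_sd, -np.inf, thr - 1e-3, len(idx[0])
        )
        achieved = count / n_lobe
        if target > 0 and abs(achieved - target) > 0.2 * target:
            raise PhantomInfeasibleError(
                f"lobe {name}: achieved fraction {achieved:.4f} outside ±20% of {target}"
            )

    return LabeledVolume(image=image, lobes=labels, spacing=spec.spacing)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Generating coefficients for the pulmonary-function outcomes of the COPD
#: group, per unit of (LAA%, HI+, HI−, age, male, pack-years).
COPD_OUTCOME_COEFS: dict[str, tuple[float, ...]] = {
    "fev1_pct_pred": (-1.54, 0.28, 0.02, 0.73, 9.53, -0.02),
    "fev1_fvc_pct": (-1.09, 0.09, -0.03, 0.06, 2.47, 0.00),
    "rv_tlc_pct": (0.58, -0.15, 0.16, 0.05, -7.30, -0.02),
    "dlco_pct_pred": (-1.43, -0.11, 0.19, 0.18, 6.46, -0.01),
}

#: Same, for the non-COPD group.
NONCOPD_OUTCOME_COEFS: dict[str, tuple[float, ...]] = {
    "fev1_pct_pred": (-0.82, 0.08, -0.40, 0.47, 2.27, -0.04),
    "fev1_fvc_pct": (-0.78, -0.04, -0.03, -0.16, -0.30, 0.00),
    "rv_tlc_pct": (0.54, -0.06, -0.01, 0.43, -5.38, 0.00),
    "dlco_pct_pred": (-1.37, -0.11, -0.60, -0.27, 5.21, -0.09),
}

#: Generating odds ratios of the GOLD III–IV logistic model (COPD group),
#: same covariate order.
GOLD_ODDS_RATIOS: tuple[float, ...] = (1.28, 0.95, 1.03, 0.88, 0.25, 1.00)

_COVARIATE_ORDER = ("laa_pct", "hi_pos", "hi_neg", "age", "male", "pack_years")


@dataclass
class GroupParams:
    """Covariate distribution of one cohort stratum.

    Continuous covariates are parameterised by median and IQR; skewed
    ones (pack-years, LAA%) are lognormal, symmetric ones (age) normal.
    ``outcome_centers`` anchor the generated outcome medians.
    """

    male_fraction: float
    age_median: float
    age_iqr: tuple[float, float]
    pack_years_median: float
    pack_years_iqr: tuple[float, float]
    laa_median: float
    laa_iqr: tuple[float, float]
    hi_positive_mass: float = 0.8
    hi_pos_loc: float = 28.0  # location/scale of |HI| on each side of 0
    hi_pos_scale: float = 20.0
    hi_neg_loc: float = 10.0
    hi_neg_scale: float = 10.0
    outcome_centers: dict[str, float] = field(default_factory=dict)
    outcome_coefs: dict[str, tuple[float, ...]] = field(default_factory=dict)


def copd_group_params() -> GroupParams:
    return GroupParams(
        male_fraction=0.65,
        age_median=67, age_iqr=(61, 70),
        pack_years_median=57, pack_years_iqr=(40, 77),
        laa_median=4.5, laa_iqr=(1.5, 12.2),
        outcome_centers={
            "fev1_pct_pred": 71, "fev1_fvc_pct": 61,
            "rv_tlc_pct": 43, "dlco_pct_pred": 61,
        },
        outcome_coefs=dict(COPD_OUTCOME_COEFS),
    )


def noncopd_group_params() -> GroupParams:
    return GroupParams(
        male_fraction=0.51,
        age_median=63, age_iqr=(60, 67),
        pack_years_median=45, pack_years_iqr=(32, 63),
        laa_median=0.5, laa_iqr=(0.2, 1.3),
        outcome_centers={
            "fev1_pct_pred": 98, "fev1_fvc_pct": 77,
            "rv_tlc_pct": 36, "dlco_pct_pred": 82,
        },
        outcome_coefs=dict(NONCOPD_OUTCOME_COEFS),
    )


@dataclass
class CohortSpec:
    """Parameters of a simulated cross-sectional cohort.

    Outcomes are generated as linear predictor + Gaussian noise, with
    hinge terms HI⁺ = max(0, HI) and HI⁻ = min(0, HI) so the generating
    model matches the piecewise analysis.  ``residual_sd`` maps outcome
    name to noise SD; an absent entry defaults to the SD of the linear
    predictor itself, so covariates explain about half the variance.
    GOLD III–IV membership is a Bernoulli draw from the logistic model;
    its intercept is tuned so the expected prevalence among COPD subjects
    is ``gold_severe_prevalence`` unless given explicitly.
    """

    n: int = 350
    copd_fraction: float = 160 / 350
    copd: GroupParams = field(default_factory=copd_group_params)
    noncopd: GroupParams = field(default_factory=noncopd_group_params)
    residual_sd: dict[str, float] = field(default_factory=dict)
    gold_odds_ratios: tuple[float, ...] = GOLD_ODDS_RATIOS
    gold_severe_prevalence: float = 0.26
    gold_logit_intercept: float | None = None
    lr_hi_noise_sd: float = 8.0  # left/right HI scatter around whole-lung HI
    br_positive_rate: float = 0.0  # bronchodilator responders (pre-exclusion cohorts)
    cb_rate: float = 0.0
    cb_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name, frac in (
            ("copd_fraction", self.copd_fraction),
            ("br_positive_rate", self.br_positive_rate),
            ("cb_rate", self.cb_rate),
            ("cb_missing_rate", self.cb_missing_rate),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(sd < 0 for sd in self.residual_sd.values()):
            raise ValueError("residual SDs must be >= 0")


def _lognormal(rng, median, iqr, size):
    sigma = math.log(iqr[1] / iqr[0]) / (2 * 0.6744897501960817)
    return np.exp(rng.normal(math.log(median), sigma, size))


def _draw_hi(rng: np.random.Generator, p: GroupParams, size: int) -> np.ndarray:
    """Mixture of an upper-dominant (HI > 0) and lower-dominant (HI ≤ 0) part."""
    positive = rng.random(size) < p.hi_positive_mass
    hi = np.empty(size)
    n_pos = int(positive.sum())
    hi[positive] = _truncated_normal(rng, p.hi_pos_loc, p.hi_pos_scale, 1e-9, 100, n_pos)
    hi[~positive] = -_truncated_normal(
        rng, p.hi_neg_loc, p.hi_neg_scale, 0, 100, size - n_pos
    )
    return hi


def _group_frame(
    rng: np.random.Generator, p: GroupParams, n: int, spec: CohortSpec, copd: bool
) -> pd.DataFrame:
    age_sd = (p.age_iqr[1] - p.age_iqr[0]) / 1.349
    age = rng.normal(p.age_median, age_sd, n)
    male = (rng.random(n) < p.male_fraction).astype(int)
    pack_years = np.clip(_lognormal(rng, p.pack_years_median, p.pack_years_iqr, n), 10, 200)
    laa = np.clip(_lognormal(rng, p.laa_median, p.laa_iqr, n), 0.0, 60.0)
    hi = _draw_hi(rng, p, n)
    hi_left = np.clip(hi + rng.normal(0, spec.lr_hi_noise_sd, n), -100, 100)
    hi_right = np.clip(hi + rng.normal(0, spec.lr_hi_noise_sd, n), -100, 100)

    X = np.column_stack(
        [laa, np.maximum(hi, 0), np.minimum(hi, 0), age, male, pack_years]
    )
    df = pd.DataFrame(
        {
            "copd": int(copd),
            "age": age,
            "male": male,
            "pack_years": pack_years,
            "laa_pct": laa,
            "hi_pct": hi,
            "hi_left_pct": hi_left,
            "hi_right_pct": hi_right,
        }
    )
    for outcome, coefs in p.outcome_coefs.items():
        lp = X @ np.asarray(coefs)
        intercept = p.outcome_centers.get(outcome, 0.0) - (lp.mean() if n else 0.0)
        sd = spec.residual_sd.get(outcome)
        if sd is None:
            sd = float(lp.std()) if n > 1 else 0.0
        df[outcome] = intercept + lp + (rng.normal(0, sd, n) if sd > 0 else 0.0)

    if copd and n:
        df["gold_stage"] = _draw_gold_stage(rng, spec, X, df["fev1_pct_pred"].to_numpy())
    else:
        df["gold_stage"] = "none"

    # spirometry in litres: post-bronchodilator from %predicted, pre from the
    # bronchodilator-response status (responders gain >= 12% and >= 200 ml)
    pred_normal = np.clip(rng.normal(3.0, 0.45, n), 1.5, None)
    post = np.clip(df["fev1_pct_pred"].to_numpy() / 100.0, 0.1, None) * pred_normal
    responder = rng.random(n) < spec.br_positive_rate
    rel = np.where(
        responder, rng.uniform(0.15, 0.30, n), rng.uniform(0.0, 0.08, n)
    )
    pre = post / (1 + rel)
    pre = np.where(responder, np.minimum(pre, post - 0.21), pre)
    df["fev1_pre_l"] = np.clip(pre, 0.05, None)
    df["fev1_post_l"] = post

    u = rng.random(n)
    cb = np.where(
        u < spec.cb_rate, "yes", np.where(u < spec.cb_rate + spec.cb_missing_rate, "", "no")
    )
    df["cb"] = cb
    return df


def _draw_gold_stage(
    rng: np.random.Generator, spec: CohortSpec, X: np.ndarray, fev1_pct: np.ndarray
) -> np.ndarray:
    beta = np.log(np.asarray(spec.gold_odds_ratios))
    offsets = X @ beta
    c = spec.gold_logit_intercept
    if c is None:
        c = _tune_intercept(offsets, spec.gold_severe_prevalence)
    if np.isneginf(c):
        severe = np.zeros(len(X), dtype=bool)
    elif np.isposinf(c):
        severe = np.ones(len(X), dtype=bool)
    else:
        severe = rng.random(len(X)) < expit(c + offsets)
    stage = np.where(
        severe,
        np.where(fev1_pct < 30, "IV", "III"),
        np.where(fev1_pct >= 80, "I", "II"),
    )
    return stage


def _tune_intercept(offsets: np.ndarray, prevalence: float) -> float:
    """Intercept c with mean(expit(c + offsets)) = prevalence."""
    f = lambda c: float(np.mean(expit(c + offsets))) - prevalence
    return brentq(f, -200.0, 200.0)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table, one row per subject.

    Returns a schema-valid DataFrame (see :mod:`emphyhet.io`); any
    non-finite generated value raises rather than propagating silently.
    """
    rng = np.random.default_rng(spec.seed)
    n_copd = int(round(spec.n * spec.copd_fraction))
    parts = [
        _group_frame(rng, spec.copd, n_copd, spec, copd=True),
        _group_frame(rng, spec.noncopd, spec.n - n_copd, spec, copd=False),
    ]
    df = pd.concat(parts, ignore_index=True)
    df.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(df))])

    numeric = df.select_dtypes(include=[np.number])
    if not np.isfinite(numeric.to_numpy(dtype=float)).all():
        bad = numeric.columns[~np.isfinite(numeric.to_numpy(dtype=float)).all(axis=0)]
        raise FloatingPointError(f"non-finite generated values in {list(bad)}")

    from .io import COHORT_SCHEMA, validate_cohort

    report = validate_cohort(df, COHORT_SCHEMA)
    if not report.ok:
        raise AssertionError(f"generated cohort fails validation: {report.issues[:5]}")
    return df[[c.name for c in COHORT_SCHEMA.columns]]
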