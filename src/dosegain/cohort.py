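"""Synthetic paired prone/supine cohorts for end-to-end pipeline testing.

No public dataset exists for dual-CT prone/supine breast planning, so this
module generates one with the statistical structure the analysis assumes:

* per-structure voxel dose samples drawn from a two-component mixture —
  an in-field fraction near a plateau dose plus an exponentially decaying
  out-of-field bath — rolled up to cumulative DVHs on a fine dose grid;
* patient characteristics (age, BMI, breast volumes, breast depths, lung
  and heart volumes, couch, preference, tumor location) matching the
  location and spread of a dual-planning left-breast cohort;
* a pendulousness link: the prone in-field fractions of the ipsilateral
  lung and of the heart decrease with the breast depth ratio prone/supine,
  so patients with pendulous breasts genuinely gain from the prone setup
  through the dose model, not through a pasted-on label;
* optional gross outliers — patients with low depth ratio whose prone heart
  dose is inflated — mirroring the handful of clinical cases where the
  prone plan fails badly despite the trend.

Default dose-model parameters are calibrated so that cohort-mean MADDs land
near the clinically observed anchors (ipsilateral lung about 7.6% of the
prescription supine vs about 1.9% prone; heart higher prone than supine;
contralateral breast higher prone).  A fast ``direct`` link mode skips the
voxel simulation and draws the paired penalty scores from an explicit
linear model in the depth ratio, for unit tests and calibration studies
where the exact planted slope must be known.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .dvh import FRACTION, PERCENT, STRUCTURE_ROLES, STRUCTURES, StructureDVH
from .errors import ConfigError

RATIO_REF = 1.7  # median planted depth ratio; dose-link pivots around it


@dataclass(frozen=True)
class DoseModel:
    """Mixture dose model of one structure under one setup.

    A fraction ``in_field_fraction`` of the voxels sits on a plateau
    ``Normal(in_field_mu, in_field_sigma)`` (percent of prescription); the
    rest receives an exponential low-dose bath with mean ``out_field_scale``.
    ``ratio_coef`` is the log-linear sensitivity of the in-field fraction to
    the breast depth ratio (centered at :data:`RATIO_REF`).

    Between-patient heterogeneity has two layers of mean-one lognormal
    jitter on the in-field fraction: an anatomical factor shared by the two
    setups of a patient (sd ``frac_jitter`` — large lungs stay large in both
    positions) and an independent per-setup planning factor (sd
    ``setup_jitter``).  The bath scale gets the same treatment with
    ``scale_jitter`` shared and a fixed small per-setup component.
    """

    in_field_fraction: float
    in_field_mu: float
    in_field_sigma: float
    out_field_scale: float
    ratio_coef: float = 0.0
    frac_jitter: float = 0.4
    setup_jitter: float = 0.15
    scale_jitter: float = 0.3

    def fraction_for(self, ratio: float) -> float:
        f = self.in_field_fraction * math.exp(self.ratio_coef * (ratio - RATIO_REF))
        return min(max(f, 0.0), 1.0)


# Calibration: expected OAR MADD = f*mu + (1-f)*scale (MADD with reference 0
# is the mean dose).  Ipsilateral structures are on the left.
DEFAULT_DOSE_MODELS: Mapping[tuple[str, str], DoseModel] = {
    ("lung_left", "supine"): DoseModel(0.072, 95.0, 8.0, 1.2),
    ("lung_left", "prone"): DoseModel(0.011, 95.0, 8.0, 0.8, ratio_coef=-1.5),
    ("lung_right", "supine"): DoseModel(0.002, 90.0, 8.0, 0.6),
    ("lung_right", "prone"): DoseModel(0.002, 90.0, 8.0, 0.85),
    ("heart", "supine"): DoseModel(0.015, 60.0, 10.0, 1.0),
    ("heart", "prone"): DoseModel(0.040, 60.0, 10.0, 1.0, ratio_coef=-0.5),
    ("breast_right", "supine"): DoseModel(0.0, 90.0, 8.0, 0.8),
    ("breast_right", "prone"): DoseModel(0.006, 90.0, 8.0, 1.15),
    ("breast_left", "supine"): DoseModel(
        0.975, 100.3, 2.2, 30.0, frac_jitter=0.01, setup_jitter=0.005
    ),
    ("breast_left", "prone"): DoseModel(
        0.970, 99.6, 2.4, 30.0, frac_jitter=0.01, setup_jitter=0.005
    ),
    ("tumor_bed", "supine"): DoseModel(
        0.999, 101.0, 1.2, 50.0, frac_jitter=0.001, setup_jitter=0.001
    ),
    ("tumor_bed", "prone"): DoseModel(
        0.998, 100.6, 1.5, 50.0, frac_jitter=0.001, setup_jitter=0.001
    ),
    ("body", "supine"): DoseModel(0.055, 95.0, 6.0, 1.0),
    ("body", "prone"): DoseModel(0.048, 95.0, 6.0, 1.0),
}


def _mean_one_lognormal(rng: np.random.Generator, sd: float, size=None):
    """Lognormal multiplier with unit mean (keeps calibration anchors unbiased)."""
    return rng.lognormal(-0.5 * sd * sd, sd, size)


@dataclass(frozen=True)
class DirectLink:
    """Explicit linear model for the fast no-voxel mode:

    delta = intercept + slope * depth_ratio
            + supine_coef * (supine - supine_median) + Normal(0, noise_sd).

    ``supine_coef < 0`` encodes that a high supine penalty is what the prone
    setup tends to fix (regression toward the mean between paired plans).
    """

    slope: float = -0.8
    intercept: float = 1.3
    noise_sd: float = 0.35
    supine_median: float = 2.36
    supine_sigma: float = 0.25
    supine_coef: float = -0.5


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohort."""

    n_patients: int = 116
    seed: int = 12345
    mode: str = "dose"  # "dose" (voxel simulation) or "direct" (fast link)
    prescribed_dose_gy: float = 47.25
    n_voxels: int = 10_000
    grid_width: float = 0.1  # DVH export bin width, % of prescription
    dose_models: Mapping[tuple[str, str], DoseModel] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_MODELS)
    )
    link: DirectLink = field(default_factory=DirectLink)
    n_outliers: int = 3
    outlier_magnitude: float = 5.0  # upward penalty shift, % of prescription

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.grid_width <= 0:
            raise ConfigError("grid width must be positive")
        if self.mode not in ("dose", "direct"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for (s, setup), m in self.dose_models.items():
            if not 0.0 <= m.in_field_fraction <= 1.0:
                raise ConfigError(f"in-field fraction of {s}/{setup} outside [0,1]")
        if self.n_outliers < 0:
            raise ConfigError("n_outliers must be non-negative")


@dataclass
class CohortData:
    """A generated cohort: DVHs, characteristics, and the planted truths."""

    dvhs: dict[tuple[str, str], dict[str, StructureDVH]]
    characteristics: pd.DataFrame
    manifest: dict
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# characteristics
# ---------------------------------------------------------------------------

_TUMOR_LOCATIONS = (
    "lower_inner",
    "central",
    "upper_inner",
    "upper_outer",
    "lower_outer",
    "other",
)
_TUMOR_PROBS = np.array([2, 4, 11, 57, 8, 34], dtype=float) / 116.0


def sample_characteristics(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the pre-dosimetry characteristics table.

    Continuous variables use shifted lognormals / clipped normals located at
    the medians and spanning the ranges typical of a dual-planning
    left-breast cohort (age median 57.5y, BMI 25, left breast volume 484 mL,
    heart volume 461 mL); breast depths are lognormal with the prone/supine
    ratio sampled around 1.7.  BMI, weight, and setup preference carry
    realistic missingness.
    """
    n = config.n_patients
    pid = np.array([f"P{i + 1:03d}" for i in range(n)])
    age = np.clip(rng.normal(57.5, 10.0, n), 36, 82).round(0)
    height = np.clip(rng.normal(161.0, 6.5, n), 145, 185).round(0)
    bmi = np.clip(rng.lognormal(math.log(25.0), 0.17, n), 17, 43)
    weight = np.clip(bmi * (height / 100.0) ** 2, 41, 111)
    vol_left = np.clip(rng.lognormal(math.log(484.0), 0.62, n), 34, 1580)
    vol_right = np.clip(
        vol_left * rng.lognormal(math.log(597.0 / 484.0), 0.15, n), 50, 2138
    )
    depth_supine = np.clip(rng.lognormal(math.log(45.0), 0.25, n), 18, 95)
    ratio = np.clip(rng.lognormal(math.log(RATIO_REF), 0.25, n), 1.0, 3.5)
    depth_prone = ratio * depth_supine
    heart_volume = np.clip(rng.normal(461.0, 80.0, n), 259, 687)
    lung_right_vol = np.clip(rng.lognormal(math.log(2.6), 0.20, n), 1.2, 4.5)
    lung_left_vol = np.clip(rng.lognormal(math.log(2.2), 0.20, n), 1.0, 4.0)
    lad = np.clip(rng.lognormal(math.log(5.0), 0.7, n), 0.5, 35)
    couch = np.where(rng.random(n) < 0.147, "varian", "bionix")
    preference = rng.choice(
        ["supine", "none", "prone"], size=n, p=[0.526, 0.179, 0.295]
    )
    location = rng.choice(_TUMOR_LOCATIONS, size=n, p=_TUMOR_PROBS)

    frame = pd.DataFrame(
        {
            "patient_id": pid,
            "age": age,
            "height": height,
            "weight": weight,
            "bmi": bmi,
            "tumor_location": location,
            "breast_volume_left": vol_left,
            "breast_volume_right": vol_right,
            "breast_depth_supine": depth_supine,
            "breast_depth_prone": depth_prone,
            "heart_volume": heart_volume,
            "lung_volume_right": lung_right_vol,
            "lung_volume_left": lung_left_vol,
            "lad_chest_distance": lad,
            "couch": couch,
            "preference": preference,
        }
    )
    frame["lung_volume_total"] = frame["lung_volume_right"] + frame["lung_volume_left"]
    # realistic availability: BMI 95/116, weight 107/116, preference 78/116
    for col, available in (("bmi", 95 / 116), ("weight", 107 / 116), ("preference", 78 / 116)):
        miss = rng.random(n) >= available
        frame.loc[miss, col] = np.nan if col != "preference" else None
    return frame


# ---------------------------------------------------------------------------
# voxel dose simulation and DVH roll-up
# ---------------------------------------------------------------------------

def simulate_structure_doses(
    config: GeneratorConfig,
    structure: str,
    setup: str,
    rng: np.random.Generator,
    *,
    ratio: float = RATIO_REF,
    frac_multiplier: float = 1.0,
    scale_multiplier: float = 1.0,
) -> np.ndarray:
    """Draw one structure's voxel dose sample (percent of prescription)."""
    try:
        model = config.dose_models[(structure, setup)]
    except KeyError:
        raise ConfigError(f"no dose model for {structure!r}/{setup!r}") from None
    n = config.n_voxels
    f = min(max(model.fraction_for(ratio) * frac_multiplier, 0.0), 1.0)
    n_in = int(round(f * n))
    doses = np.empty(n)
    if n_in:
        doses[:n_in] = np.clip(
            rng.normal(model.in_field_mu, model.in_field_sigma, n_in), 0.0, None
        )
    if n - n_in:
        scale = model.out_field_scale * scale_multiplier
        bath = rng.exponential(scale, n - n_in)
        # scatter dose: truncate the tail at six mean-lengths, below the plateau
        doses[n_in:] = np.minimum(bath, min(6.0 * scale, model.in_field_mu))
    return doses


def voxels_to_dvh(
    voxels: np.ndarray,
    structure: str,
    grid_width: float,
    total_volume: float = 1.0,
) -> StructureDVH:
    """Roll a voxel dose sample up to a cumulative DVH on a regular grid.

    Grid points run from 0 to the maximum voxel dose in steps of
    ``grid_width``; the volume at each grid dose is the fraction of voxels
    receiving at least that dose, scaled by ``total_volume``.
    """
    edges = np.arange(0.0, float(np.max(voxels)) + 2 * grid_width, grid_width)
    counts, _ = np.histogram(voxels, bins=edges)
    at_least = voxels.size - np.concatenate([[0], np.cumsum(counts)])
    volumes = total_volume * at_least[:-1] / voxels.size
    doses = edges[:-1]
    last = int(np.nonzero(volumes)[0][-1]) + 1
    return StructureDVH(
        structure_name=structure,
        role=STRUCTURE_ROLES.get(structure, "OAR"),
        doses=doses[:last],
        volumes=volumes[:last],
        total_volume=total_volume,
        dose_unit=PERCENT,
        volume_unit=FRACTION,
    )


def expected_madd(model: DoseModel, role: str, ratio: float = RATIO_REF) -> float:
    """Noise-free expected MADD under a dose model (reference 0 for OAR/body,
    100 for a PTV), used to derive the planted link slope."""
    f = model.fraction_for(ratio)
    if role == "PTV":
        a = model.in_field_mu - 100.0
        s = model.in_field_sigma
        from scipy.stats import norm

        folded = s * math.sqrt(2 / math.pi) * math.exp(-(a**2) / (2 * s**2)) + a * (
            1 - 2 * norm.cdf(-a / s)
        )
        # out-of-field bath sits far below the prescription
        return f * folded + (1 - f) * (100.0 - model.out_field_scale)
    return f * model.in_field_mu + (1 - f) * model.out_field_scale


def expected_delta(config: GeneratorConfig, ratio: float, weights: Mapping[str, float]) -> float:
    """Noise-free expected penalty difference prone - supine at a depth ratio."""
    total = 0.0
    for s, w in weights.items():
        if w <= 0:
            continue
        role = STRUCTURE_ROLES[s]
        mp = expected_madd(config.dose_models[(s, "prone")], role, ratio)
        ms = expected_madd(config.dose_models[(s, "supine")], role, ratio)
        total += w * (mp - ms)
    return total


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig, outdir=None) -> CohortData:
    """Generate a paired cohort; deterministic for a fixed config and seed.

    In ``dose`` mode every patient gets voxel-simulated doses for the seven
    structures in both setups, rolled to DVHs; penalty scores are *not*
    attached here — they flow through the real MADD/penalty pipeline
    downstream.  In ``direct`` mode paired type-1 penalty scores are drawn
    from the explicit link model instead (no DVHs).  The manifest records
    the planted truths: the effective linear slope of the expected penalty
    difference on the depth ratio, and the planted outlier ids.

    When ``outdir`` is given the DVH and characteristics CSVs plus a JSON
    manifest are written there.
    """
    rng = np.random.default_rng(config.seed)
    chars = sample_characteristics(config, rng)
    manifest: dict = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "mode": config.mode,
        "outlier_ids": [],
        "outlier_magnitude": config.outlier_magnitude,
    }
    cohort = CohortData(dvhs={}, characteristics=chars, manifest=manifest, config=config)

    if config.mode == "direct":
        link = config.link
        ratio = chars["breast_depth_prone"] / chars["breast_depth_supine"]
        supine = rng.lognormal(math.log(link.supine_median), link.supine_sigma, len(chars))
        delta = (
            link.intercept
            + link.slope * ratio.to_numpy()
            + link.supine_coef * (supine - link.supine_median)
            + rng.normal(0.0, link.noise_sd, len(chars))
        )
        chars["supine_score"] = supine
        chars["prone_score"] = supine + delta
        chars["delta_penalty"] = delta
        manifest["planted_slope"] = link.slope
        manifest["planted_intercept"] = link.intercept
    else:
        from .penalty import builtin_weights

        type1 = builtin_weights("type1").weights
        ratios = (
            chars["breast_depth_prone"] / chars["breast_depth_supine"]
        ).to_numpy()
        for i, pid in enumerate(chars["patient_id"]):
            # anatomical susceptibility, shared by the two setups
            shared_f = {
                s: _mean_one_lognormal(rng, config.dose_models[(s, "supine")].frac_jitter)
                for s in STRUCTURES
            }
            shared_s = {
                s: _mean_one_lognormal(rng, config.dose_models[(s, "supine")].scale_jitter)
                for s in STRUCTURES
            }
            for setup in ("supine", "prone"):
                structs = {}
                for s in STRUCTURES:
                    model = config.dose_models[(s, setup)]
                    fm = shared_f[s] * _mean_one_lognormal(rng, model.setup_jitter)
                    sm = shared_s[s] * _mean_one_lognormal(rng, 0.1)
                    voxels = simulate_structure_doses(
                        config, s, setup, rng,
                        ratio=ratios[i], frac_multiplier=fm, scale_multiplier=sm,
                    )
                    structs[s] = voxels_to_dvh(voxels, s, config.grid_width)
                cohort.dvhs[(pid, setup)] = structs
        # effective planted slope: linear approximation of the noise-free
        # expected delta over the sampled ratio distribution
        exp_d = np.array([expected_delta(config, r, type1) for r in ratios])
        if np.unique(ratios).size >= 2:
            slope, intercept = np.polyfit(ratios, exp_d, 1)
        else:  # degenerate cohort: central difference of the link at the pivot
            h = 0.1
            slope = (
                expected_delta(config, RATIO_REF + h, type1)
                - expected_delta(config, RATIO_REF - h, type1)
            ) / (2 * h)
            intercept = exp_d[0] - slope * ratios[0]
        manifest["planted_slope"] = float(slope)
        manifest["planted_intercept"] = float(intercept)

    k = min(config.n_outliers, config.n_patients - 1)
    if k > 0:
        cohort = plant_outliers(
            cohort, k, config.outlier_magnitude,
            rng=np.random.default_rng(config.seed + 1),
        )

    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def plant_outliers(
    cohort: CohortData,
    k: int,
    magnitude: float,
    rng: np.random.Generator | None = None,
) -> CohortData:
    """Turn ``k`` patients into gross prone failures.

    Their penalty difference is shifted upward by about ``magnitude``
    (percent of prescription) and their depth ratio is forced below 1.5 —
    low-pendulousness patients whose prone plan fails badly, off the trend.
    In dose mode the shift is realised physically, by regenerating the prone
    heart dose sample with an inflated in-field fraction; in direct mode it
    is added to the planted delta.  Outlier ids are recorded in the
    manifest.
    """
    n = len(cohort.characteristics)
    if k >= n:
        raise ConfigError(f"cannot plant {k} outliers in a cohort of {n}")
    if k == 0:
        return cohort
    if rng is None:
        rng = np.random.default_rng(cohort.config.seed + 1)
    # do not mutate the input cohort
    cohort = CohortData(
        dvhs={k: dict(v) for k, v in cohort.dvhs.items()},
        characteristics=cohort.characteristics,
        manifest=dict(cohort.manifest),
        config=cohort.config,
    )
    chars = cohort.characteristics
    ids = list(rng.choice(chars["patient_id"].to_numpy(), size=k, replace=False))
    mask = chars["patient_id"].isin(ids)
    new_ratio = rng.uniform(1.0, 1.5, int(mask.sum()))
    chars = chars.copy()
    chars.loc[mask, "breast_depth_prone"] = (
        chars.loc[mask, "breast_depth_supine"].to_numpy() * new_ratio
    )
    cohort = replace_characteristics(cohort, chars)
    config = cohort.config
    if config.mode == "direct":
        chars.loc[mask, "delta_penalty"] = (
            chars.loc[mask, "delta_penalty"].to_numpy() + magnitude
        )
        chars.loc[mask, "prone_score"] = (
            chars.loc[mask, "supine_score"].to_numpy()
            + chars.loc[mask, "delta_penalty"].to_numpy()
        )
    else:
        from .penalty import builtin_weights

        w_heart = builtin_weights("type1").weights["heart"]
        model = config.dose_models[("heart", "prone")]
        extra_f = magnitude / (w_heart * (model.in_field_mu - model.out_field_scale))
        boosted = replace(
            model,
            in_field_fraction=min(model.in_field_fraction + extra_f, 1.0),
            ratio_coef=0.0,
        )
        boosted_config = replace_dose_model(config, ("heart", "prone"), boosted)
        for pid in ids:
            voxels = simulate_structure_doses(boosted_config, "heart", "prone", rng)
            cohort.dvhs[(pid, "prone")]["heart"] = voxels_to_dvh(
                voxels, "heart", config.grid_width
            )
    cohort.manifest["outlier_ids"] = [str(p) for p in ids]
    cohort.manifest["outlier_magnitude"] = magnitude
    return cohort


def replace_characteristics(cohort: CohortData, chars: pd.DataFrame) -> CohortData:
    return CohortData(
        dvhs=cohort.dvhs,
        characteristics=chars,
        manifest=cohort.manifest,
        config=cohort.config,
    )


def replace_dose_model(
    config: GeneratorConfig, key: tuple[str, str], model: DoseModel
) -> GeneratorConfig:
    models = dict(config.dose_models)
    models[key] = model
    return replace(config, dose_models=models)


def write_cohort(cohort: CohortData, outdir) -> None:
    """Write characteristics CSV, DVH CSV (dose mode), and the manifest."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.characteristics.to_csv(outdir / "characteristics.csv", index=False)
    if cohort.dvhs:
        from .dvh import write_dvh_csv

        write_dvh_csv(cohort.dvhs, outdir / "dvhs.csv", dose_unit=PERCENT)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, indent=2, sort_keys=True)
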