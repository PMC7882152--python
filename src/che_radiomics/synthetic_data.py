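"""Synthetic two-class cohort generator: ROI volumes plus clinical table.

Emulates the statistical structure the downstream analysis assumes for a
cirrhosis cohort with and without covert hepatic encephalopathy (CHE /
nCHE): per-subject ROI image volumes whose intensity location, spread and
spatial texture can differ by class, and clinical covariates (venous blood
ammonia NH3, Child-Pugh stage, NCT-A, DST, age, sex, education) with
class-conditional distributions.

Each ROI volume is a Gaussian random field — white noise convolved with an
isotropic Gaussian kernel — so the class knobs map interpretably onto the
feature families: ``intensity_shift`` moves the histogram (Median/Mean),
``variance_ratio`` scales the spread (Variance), and ``smoothness_ratio``
scales the autocorrelation length, to which GLCM/GLRLM texture responds.
Effects apply only inside ``effect_rois``.  Masks are axis-aligned
ellipsoids inscribed in the grid, so run-length handling is exercised
across non-box mask boundaries.

Default cohort sizes (54 CHE / 52 nCHE), the 10 precuneus ROI names, and
the clinical distributions follow the training-set characteristics of the
study population being emulated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging_io import ImageVolume, ROIMask, write_volume

ROI_NAMES_10 = tuple(
    f"{side}-{region}"
    for side in ("right", "left")
    for region in ("PC", "PEp", "PEm", "PEr", "Lc1")
)

#: Class-conditional clinical distributions: continuous as (mean, sd),
#: Child-Pugh as P(A/B/C), sex as P(M).  CHE column then nCHE column.
DEFAULT_CLINICAL_PARAMS: dict = {
    "nh3": {"CHE": (57.43, 44.45), "nCHE": (21.36, 12.13), "dist": "lognormal"},
    "nct_a": {"CHE": (63.65, 32.00), "nCHE": (31.37, 7.26), "dist": "truncnormal"},
    "dst": {"CHE": (24.51, 11.59), "nCHE": (38.53, 9.18), "dist": "truncnormal"},
    "age": {"CHE": (57.0, 9.98), "nCHE": (53.22, 8.99), "dist": "truncnormal"},
    "education": {"CHE": (7.95, 4.26), "nCHE": (9.89, 3.03), "dist": "truncnormal"},
    "child_pugh": {"CHE": (8 / 37, 13 / 37, 16 / 37),
                   "nCHE": (21 / 36, 12 / 36, 3 / 36)},
    "sex": {"CHE": 25 / 37, "nCHE": 23 / 36},
}


class ConfigError(ValueError):
    pass


@dataclass
class CohortConfig:
    n_che: int = 54
    n_nche: int = 52
    roi_names: tuple[str, ...] = ROI_NAMES_10
    roi_shape: tuple[int, int, int] = (24, 24, 24)
    effect_rois: tuple[str, ...] = ("right-Lc1", "right-PEp")
    intensity_shift: float = 15.0
    variance_ratio: float = 1.2
    smoothness_ratio: float = 1.15
    baseline_mean: float = 500.0
    baseline_sd: float = 100.0
    baseline_smoothness: float = 1.0     # Gaussian kernel sigma, voxels
    # between-subject biological variability (applies to both classes):
    # additive sd of the per-subject field mean, and log-normal sd of the
    # per-subject voxel-sd and smoothing-length multipliers
    subject_mean_sd: float = 40.0
    subject_sd_jitter: float = 0.25
    subject_smoothness_jitter: float = 0.2
    clinical_params: dict = field(default_factory=lambda: DEFAULT_CLINICAL_PARAMS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_che < 2 or self.n_nche < 2:
            raise ConfigError("need at least 2 subjects per class")
        unknown = set(self.effect_rois) - set(self.roi_names)
        if unknown:
            raise ConfigError(f"effect_rois not in roi_names: {sorted(unknown)}")
        for name, v in (("variance_ratio", self.variance_ratio),
                        ("smoothness_ratio", self.smoothness_ratio)):
            if v <= 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        if min(self.roi_shape) < 8:
            raise ConfigError(
                f"roi_shape {self.roi_shape} too small for the smoothing kernel "
                "(each axis must be >= 8 voxels)")
        for key in ("child_pugh",):
            for cls in ("CHE", "nCHE"):
                probs = self.clinical_params[key][cls]
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ConfigError(
                        f"{key} probabilities for {cls} sum to {sum(probs)}")


def _subject_rng(master_seed: int, *keys) -> np.random.Generator:
    """Independent, reproducible stream per (seed, subject, ROI) counter key.

    String keys are hashed so streams do not collide across ROI names.
    """
    ints = []
    for k in keys:
        if isinstance(k, str):
            h = hashlib.sha256(k.encode()).digest()
            ints.append(int.from_bytes(h[:4], "little"))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence([master_seed & 0x7FFFFFFF, *ints]))


def ellipsoid_mask(shape: tuple[int, int, int], margin: int = 1) -> np.ndarray:
    """Axis-aligned ellipsoid inscribed in the grid, `margin` voxels inset."""
    grids = np.indices(shape).astype(float)
    centers = [(s - 1) / 2 for s in shape]
    semis = [(s - 1) / 2 - margin for s in shape]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centers, semis))
    return q <= 1.0


def generate_roi_volume(class_label: str, roi_name: str, config: CohortConfig,
                        subject_seed: int) -> ImageVolume:
    """One ROI volume: smoothed Gaussian white noise with class effects.

    The field is rescaled to unit marginal variance before the subject's
    voxel-sd is applied, so ``variance_ratio`` acts directly on the marginal
    spread.  Between-subject variability (random per-subject field mean,
    voxel-sd and smoothing length, identical machinery in both classes)
    keeps the class distributions overlapping the way patient cohorts do;
    the class mean shift, variance ratio and smoothing-length ratio are
    applied on top, only when ``roi_name`` is in ``config.effect_rois`` and
    the class is CHE.
    """
    if min(config.roi_shape) < 8:
        raise ConfigError("roi_shape too small for the smoothing kernel")
    rng = _subject_rng(config.seed, subject_seed, roi_name)
    # subject-level draws come first so identical (seed, subject_seed) pairs
    # share them across class labels
    mean = config.baseline_mean + config.subject_mean_sd * rng.standard_normal()
    sd = config.baseline_sd * rng.lognormal(0.0, config.subject_sd_jitter)
    sigma = config.baseline_smoothness * rng.lognormal(
        0.0, config.subject_smoothness_jitter)

    affected = class_label == "CHE" and roi_name in config.effect_rois
    if affected:
        mean += config.intensity_shift
        sd *= np.sqrt(config.variance_ratio)
        sigma *= config.smoothness_ratio

    white = rng.standard_normal(config.roi_shape)
    smooth = gaussian_filter(white, sigma=sigma, mode="wrap")
    smooth /= smooth.ravel().std() or 1.0   # unit marginal variance
    data = mean + sd * smooth
    return ImageVolume(data=data, spacing=(1.0, 1.0, 1.0),
                       subject_id=f"s{subject_seed:04d}")


def generate_clinical(class_label: str, config: CohortConfig,
                      subject_seed: int) -> dict:
    """One subject's clinical record from the class-conditional distributions.

    NH3 is log-normal re-parameterized to the configured mean/sd (positive
    support); NCT-A, DST, age and education are normal truncated at 0 (by
    resampling); Child-Pugh and sex are categorical draws.
    """
    p = config.clinical_params
    rng = _subject_rng(config.seed, subject_seed, "clinical")
    rec: dict = {"subject_id": f"s{subject_seed:04d}", "group": class_label}

    for col in ("nh3", "nct_a", "dst", "age", "education"):
        mean, sd = p[col][class_label]
        if sd == 0:
            rec[col] = float(mean)
        elif p[col].get("dist") == "lognormal" and col == "nh3":
            s2 = np.log(1 + (sd / mean) ** 2)
            mu = np.log(mean) - s2 / 2
            rec[col] = float(rng.lognormal(mu, np.sqrt(s2)))
        else:
            v = rng.normal(mean, sd)
            while v < 0:
                v = rng.normal(mean, sd)
            rec[col] = float(v)
    rec["child_pugh"] = ("A", "B", "C")[
        rng.choice(3, p=np.asarray(p["child_pugh"][class_label]))]
    rec["sex"] = "M" if rng.random() < p["sex"][class_label] else "F"
    return rec


def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Full cohort: clinical table plus per-(subject, ROI) volumes and masks.

    Subject seeds are 0..n-1 (CHE first).  If ``out_dir`` is given, each
    volume/mask pair is written as NIfTI (1 mm isotropic) under
    ``<subject>_<roi>.nii.gz`` / ``<subject>_<roi>_mask.nii.gz`` and the
    clinical table as ``clinical.csv``; re-running with the same seed
    reproduces identical CSV content.  Returns the clinical table and an
    in-memory map ``{subject_id: {roi_name: (ImageVolume, ROIMask)}}``.
    """
    labels = ["CHE"] * config.n_che + ["nCHE"] * config.n_nche
    mask_arr = ellipsoid_mask(config.roi_shape)
    records, images = [], {}
    for sseed, cls in enumerate(labels):
        rec = generate_clinical(cls, config, sseed)
        records.append(rec)
        sid = rec["subject_id"]
        images[sid] = {}
        for roi in config.roi_names:
            vol = generate_roi_volume(cls, roi, config, sseed)
            images[sid][roi] = (vol, ROIMask(name=roi, data=mask_arr))
    clinical = pd.DataFrame.from_records(records)

    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            for sid, rois in images.items():
                for roi, (vol, msk) in rois.items():
                    write_volume(out / f"{sid}_{roi}.nii.gz", vol.data)
                    write_volume(out / f"{sid}_{roi}_mask.nii.gz",
                                 msk.data.astype(np.uint8))
            clinical.to_csv(out / "clinical.csv", index=False)
        except OSError as exc:
            raise OSError(f"failed writing cohort under {out}: {exc}") from exc
    return clinical, images
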