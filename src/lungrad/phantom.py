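"""Synthetic lesion phantoms and cohorts.

This module generates everything the analysis pipeline consumes, with known
ground truth: textured lesions on noisy backgrounds (controllable circularity
via a cosine-perturbed radial boundary, controllable texture via the
correlation length of a Gaussian random field), repeat-scan pairs with added
noise and a small rigid shift, and clinical tables whose survival hazard,
semantic flags, mutation labels, and ordinal grade are statistically linked to
the image-generating parameters with stated effect sizes.

All randomness flows through one `numpy` Generator seeded per call; a fixed
seed reproduces a cohort bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .images import GrayImage, LesionMask, read_image, read_mask, write_image, write_mask

#: Exact column order of the clinical CSV.
CLINICAL_COLUMNS = [
    "subject_id", "time_months", "event", "age", "sex", "smoking",
    "stage_group", "grade", "histology", "egfr", "kras", "alk",
    "solid", "lobular", "spiculated", "juxtapleural", "pleura_tag",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of a single textured lesion phantom.

    The lesion boundary is the analytic curve
    ``r(theta) = lesion_radius * (1 + spiculation_amp * cos(spiculation_freq * theta))``
    so circularity of the ground-truth mask is controlled exactly; the lesion
    interior carries a stationary correlated Gaussian intensity field with the
    requested mean, standard deviation and correlation length.
    """

    image_size: int = 128
    pixel_spacing: float = 1.0          # mm
    lesion_radius: float = 18.0         # mm
    spiculation_amp: float = 0.0        # >= 0, dimensionless
    spiculation_freq: int = 8           # lobes per revolution
    lesion_mean: float = 180.0          # intensity units
    lesion_sd: float = 20.0
    texture_corr_len: float = 2.0       # px
    background_mean: float = 100.0
    background_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.lesion_sd < 0 or self.background_sd < 0:
            raise ValueError("intensity sd must be >= 0")
        if self.texture_corr_len < 0:
            raise ValueError("texture_corr_len must be >= 0")
        if self.spiculation_amp < 0:
            raise ValueError("spiculation_amp must be >= 0")
        max_r_mm = self.lesion_radius * (1.0 + self.spiculation_amp)
        half_frame_mm = (self.image_size / 2 - 2) * self.pixel_spacing
        if max_r_mm >= half_frame_mm:
            raise ValueError(
                f"lesion (max radius {max_r_mm:.1f} mm) does not fit inside the "
                f"frame (half-width {half_frame_mm:.1f} mm)"
            )


def _correlated_field(shape, corr_len: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-sd stationary field with spatial correlation length ~corr_len px.

    Gaussian-filtered white noise, renormalized to unit variance.
    """
    white = rng.standard_normal(shape)
    if corr_len <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=corr_len, mode="wrap")
    sd = smooth.std()
    if sd == 0:  # pathological tiny image
        return np.zeros(shape)
    return smooth / sd


def make_lesion_phantom(config: PhantomConfig) -> tuple[GrayImage, LesionMask]:
    """Generate one textured lesion image and its exact analytic support mask.

    The image is quantized to the uint16 intensity grid so that the on-disk
    16-bit TIFF round trip is exact.
    """
    n = config.image_size
    sp = config.pixel_spacing
    rng = np.random.default_rng(config.seed)

    center = (n - 1) / 2.0
    rows, cols = np.mgrid[0:n, 0:n]
    dy = (rows - center) * sp
    dx = (cols - center) * sp
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = config.lesion_radius * (
        1.0 + config.spiculation_amp * np.cos(config.spiculation_freq * theta)
    )
    mask = r <= boundary

    # additive composition: the white background/acquisition-noise field covers
    # the whole frame (lesions are imaged with noise too); the correlated
    # lesion field raises the in-mask mean to lesion_mean and adds texture
    background = config.background_mean + config.background_sd * rng.standard_normal((n, n))
    texture = _correlated_field((n, n), config.texture_corr_len, rng)
    lesion = (config.lesion_mean - config.background_mean) + config.lesion_sd * texture
    image = background + np.where(mask, lesion, 0.0)
    image = np.clip(np.round(image), 0, 65535)

    spacing = (sp, sp)
    return GrayImage(image, spacing), LesionMask(mask, spacing)


def make_repeat_pair(
    image: GrayImage,
    mask: LesionMask,
    noise_sd: float = 5.0,
    shift_px: int = 0,
    seed: int = 0,
) -> tuple[GrayImage, LesionMask]:
    """Emulate a short-interval repeat scan: added noise plus a rigid shift.

    The image and mask are translated by ``shift_px`` pixels along both axes
    (the mask identically, so lesion area is preserved) and independent
    Gaussian noise of ``noise_sd`` is added to the image.
    """
    rng = np.random.default_rng(seed)
    px = mask.pixels
    if shift_px != 0:
        rr, cc = np.nonzero(px)
        n_rows, n_cols = px.shape
        if (rr.min() + shift_px < 0 or rr.max() + shift_px >= n_rows
                or cc.min() + shift_px < 0 or cc.max() + shift_px >= n_cols):
            raise ValueError(f"shift of {shift_px} px pushes the lesion out of frame")
        shifted_img = np.roll(image.pixels, (shift_px, shift_px), axis=(0, 1))
        shifted_mask = np.roll(px, (shift_px, shift_px), axis=(0, 1))
    else:
        shifted_img = image.pixels.copy()
        shifted_mask = px.copy()
    if noise_sd > 0:
        shifted_img = shifted_img + noise_sd * rng.standard_normal(shifted_img.shape)
        shifted_img = np.clip(np.round(shifted_img), 0, 65535)
    return GrayImage(shifted_img, image.spacing), LesionMask(shifted_mask, mask.spacing)


@dataclass(frozen=True)
class CohortConfig:
    """Statistical structure of a synthetic clinical cohort.

    ``log_hr`` maps feature names to log hazard ratios per 1 SD of the
    (internally standardized) feature; survival times follow an exponential
    proportional-hazards model with independent exponential censoring whose
    rate is calibrated so the expected censored fraction equals
    ``censor_rate``.  ``semantic_link`` thresholds generating parameters into
    semantic flags, ``mutation_shift`` states feature-space mean shifts (in
    SD) between mutant and wild-type, and ``grade_link`` states the target
    Spearman correlation between a feature and the ordinal grade 1-3.
    """

    n_subjects: int = 200
    log_hr: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.02       # events / month
    censor_rate: float = 0.3
    semantic_link: dict[str, float] = field(
        default_factory=lambda: {"spiculated": 0.15, "solid": 180.0}
    )
    mutation_shift: dict[str, tuple[str, float]] = field(default_factory=dict)
    grade_link: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


_KNOWN_GENES = ("egfr", "kras", "alk")
_KNOWN_FLAGS = ("solid", "lobular", "spiculated", "juxtapleural", "pleura_tag")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def simulate_survival(features: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Draw survival outcomes from an exponential proportional-hazards model.

    Returns a DataFrame with ``subject_id``, ``time_months`` (two decimals)
    and ``event``; the linear predictor is the sum of ``log_hr[f] * z_f`` over
    the named features, standardized within the cohort.
    """
    for name in config.log_hr:
        if name not in features.columns:
            raise KeyError(f"feature '{name}' named in log_hr is missing from the table")
    n = len(features)
    rng = np.random.default_rng(config.seed)
    lp = np.zeros(n)
    for name, beta in config.log_hr.items():
        lp += beta * _standardize(features[name].to_numpy(dtype=float))
    rate = config.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / rate)

    if config.censor_rate > 0:
        # P(C < T_i) = c / (c + rate_i) for independent exponentials; calibrate
        # the common censoring rate c so the mean over subjects hits the target.
        def expected_censored(c):
            return np.mean(c / (c + rate)) - config.censor_rate

        hi = rate.max() * 1e6
        c = optimize.brentq(expected_censored, 1e-12, hi)
        censor_time = rng.exponential(1.0 / c, size=n)
    else:
        censor_time = np.full(n, np.inf)

    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(np.round(time, 2), 0.01)
    out = pd.DataFrame(
        {
            "subject_id": features.get("subject_id", pd.RangeIndex(n).map("S{:04d}".format)),
            "time_months": time,
            "event": event,
        }
    )
    return out


def _tertile_spearman(latent_r: float) -> float:
    """Large-sample Spearman between a N(0,1) feature and the tertiled latent
    ``u = r*z + sqrt(1-r^2)*eps`` (bivariate-normal closed form)."""
    c1, c2 = stats.norm.ppf([1 / 3, 2 / 3])
    rho = latent_r / math.sqrt(2.0)
    cov = [[1.0, rho], [rho, 1.0]]

    def upper(c):
        # P(X > 0, Y > c) = Phi2(0, -c; rho)
        return stats.multivariate_normal(mean=[0, 0], cov=cov).cdf([0.0, -c])

    num = sum(upper(c) - (1 - stats.norm.cdf(c)) / 2.0 for c in (c1, c2)) / 3.0
    return num / (math.sqrt(1 / 12) * math.sqrt(2 / 27))


def _calibrate_grade_corr(target: float) -> float:
    """Latent correlation whose tertiled Spearman equals ``target``."""
    limit = _tertile_spearman(0.999)
    if abs(target) >= limit:
        raise ValueError(f"grade_link {target} exceeds attainable Spearman {limit:.3f}")
    if target == 0:
        return 0.0
    return optimize.brentq(lambda r: _tertile_spearman(r) - target, -0.999, 0.999, xtol=1e-6)


def simulate_profiles(
    features: pd.DataFrame,
    phantom_params: pd.DataFrame,
    config: CohortConfig,
) -> pd.DataFrame:
    """Fill semantic, genetic and histopathological labels for each subject.

    Semantic flags are deterministic thresholds on the generating phantom
    parameters; mutation labels are drawn so mutant lesions sit ``shift`` SD
    higher on the named feature (Bayes posterior of a two-Gaussian mixture);
    grade 1-3 is a tertiled latent whose observed Spearman correlation with
    the named feature is calibrated to ``grade_link``.
    """
    n = len(features)
    rng = np.random.default_rng(config.seed + 1)
    out = pd.DataFrame(index=features.index)
    out["subject_id"] = features.get(
        "subject_id", pd.RangeIndex(n).map("S{:04d}".format)
    )

    # each semantic flag thresholds one generating parameter
    flag_param = {
        "solid": "lesion_mean",
        "lobular": "spiculation_freq",
        "spiculated": "spiculation_amp",
        "juxtapleural": "lesion_radius",
        "pleura_tag": "lesion_sd",
    }
    for flag, cutoff in config.semantic_link.items():
        if flag not in _KNOWN_FLAGS:
            raise KeyError(f"unknown semantic flag '{flag}'")
        param = flag_param[flag]
        out[flag] = (phantom_params[param].to_numpy(dtype=float) > cutoff).astype(int)
    for flag in _KNOWN_FLAGS:
        if flag not in out.columns:
            out[flag] = rng.binomial(1, 0.3, size=n)

    prevalence = {"egfr": 0.2, "kras": 0.23, "alk": 0.02}
    for gene in _KNOWN_GENES:
        if gene in config.mutation_shift:
            feat, shift = config.mutation_shift[gene]
            if feat not in features.columns:
                raise KeyError(f"mutation_shift names unknown feature '{feat}'")
            z = _standardize(features[feat].to_numpy(dtype=float))
            p = prevalence[gene]
            # posterior P(mutant | z) when z|mut ~ N(shift,1), z|wild ~ N(0,1)
            lik_m = stats.norm.pdf(z, loc=shift)
            lik_w = stats.norm.pdf(z, loc=0.0)
            post = p * lik_m / (p * lik_m + (1 - p) * lik_w)
            out[gene] = np.where(rng.random(n) < post, "mutant", "wild")
        else:
            out[gene] = np.where(rng.random(n) < prevalence[gene], "mutant", "wild")
    unknown = set(config.mutation_shift) - set(_KNOWN_GENES)
    if unknown:
        raise KeyError(f"unknown gene(s) in mutation_shift: {sorted(unknown)}")

    if config.grade_link:
        feat, target = next(iter(config.grade_link.items()))
        if feat not in features.columns:
            raise KeyError(f"grade_link names unknown feature '{feat}'")
        r = _calibrate_grade_corr(target)
        z = _standardize(features[feat].to_numpy(dtype=float))
        latent = r * z + math.sqrt(1 - r * r) * rng.standard_normal(n)
        cuts = np.quantile(latent, [1 / 3, 2 / 3])
        out["grade"] = 1 + (latent > cuts[0]).astype(int) + (latent > cuts[1]).astype(int)
    else:
        out["grade"] = rng.integers(1, 4, size=n)

    out["age"] = np.clip(np.round(rng.normal(68, 9, size=n)), 40, 90).astype(int)
    out["sex"] = np.where(rng.random(n) < 0.65, "male", "female")
    out["smoking"] = np.where(rng.random(n) < 0.55, "ever", "never")
    out["stage_group"] = np.where(rng.random(n) < 0.8, "0-IIB", "IIIA-IVB")
    out["histology"] = rng.choice(
        ["adeno", "squamous", "other"], size=n, p=[0.6, 0.3, 0.1]
    )
    return out


def write_cohort(
    directory: str | Path,
    images: list[GrayImage],
    masks: list[LesionMask],
    records: pd.DataFrame,
) -> dict[str, Path]:
    """Write a cohort to disk: 16-bit TIFF images, 8-bit PNG masks, clinical CSV.

    Returns a manifest of written paths.  Reading the files back reproduces
    the arrays exactly.
    """
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    if len(images) != len(masks):
        raise ValueError("images and masks must pair one-to-one")
    ids = (
        records["subject_id"].astype(str).tolist()
        if len(records)
        else [f"S{i:04d}" for i in range(len(images))]
    )
    paths: dict[str, Path] = {}
    for sid, img, msk in zip(ids, images, masks):
        paths[f"image/{sid}"] = write_image(directory / "images" / f"{sid}.tif", img)
        paths[f"mask/{sid}"] = write_mask(directory / "masks" / f"{sid}.png", msk)
    csv_path = directory / "clinical.csv"
    cols = [c for c in CLINICAL_COLUMNS if c in records.columns] + [
        c for c in records.columns if c not in CLINICAL_COLUMNS
    ]
    records.loc[:, cols].to_csv(csv_path, index=False)
    paths["clinical"] = csv_path
    return paths


def read_cohort(directory: str | Path):
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    records = pd.read_csv(directory / "clinical.csv")
    images, masks = [], []
    for sid in records.get("subject_id", pd.Series(dtype=str)).astype(str):
        images.append(read_image(directory / "images" / f"{sid}.tif"))
        masks.append(read_mask(directory / "masks" / f"{sid}.png"))
    return images, masks, records


def sample_phantom_configs(
    n: int,
    seed: int = 0,
    image_size: int = 128,
    pixel_spacing: float = 1.0,
) -> list[PhantomConfig]:
    """Draw a heterogeneous set of phantom configurations for a cohort.

    Radius, spiculation, texture correlation length, and lesion contrast vary
    across subjects so downstream features carry real between-subject
    variance.
    """
    rng = np.random.default_rng(seed)
    configs = []
    for i in range(n):
        configs.append(
            PhantomConfig(
                image_size=image_size,
                pixel_spacing=pixel_spacing,
                lesion_radius=float(rng.uniform(8, 22)),
                spiculation_amp=float(rng.uniform(0.0, 0.3)),
                spiculation_freq=int(rng.integers(5, 11)),
                lesion_mean=float(rng.uniform(150, 210)),
                lesion_sd=float(rng.uniform(10, 30)),
                texture_corr_len=float(rng.uniform(0.5, 6.0)),
                background_mean=100.0,
                background_sd=5.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return configs


def phantom_param_table(configs: list[PhantomConfig]) -> pd.DataFrame:
    """Tabulate generating parameters, one row per subject."""
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(len(configs))],
            "lesion_radius": [c.lesion_radius for c in configs],
            "spiculation_amp": [c.spiculation_amp for c in configs],
            "spiculation_freq": [c.spiculation_freq for c in configs],
            "lesion_mean": [c.lesion_mean for c in configs],
            "lesion_sd": [c.lesion_sd for c in configs],
            "texture_corr_len": [c.texture_corr_len for c in configs],
        }
    )
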