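"""Measurement reliability of radiomic features.

Intraclass correlation ICC(2,1) (two-way random effects, absolute agreement,
single measure) and Bland-Altman limits of agreement, applied to paired
feature measurements from repeat scans, different operators, or different
segmentation algorithms.  Features with ICC >= 0.8 are flagged robust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import ALL_FEATURE_COLUMNS, FeatureConfig, extract_all
from .images import GrayImage, LesionMask
from .segmentation import ContourParams, refine_active_contour


@dataclass(frozen=True)
class ICCEstimate:
    """ICC(2,1) with its variance components.

    Negative estimates are reported as-is (``negative`` flag set) rather
    than truncated at zero.
    """

    icc: float
    n_subjects: int
    k_measurements: int
    var_subject: float
    var_measurement: float
    var_error: float
    model: str = "two-way random, absolute agreement, single measure (ICC(2,1))"

    @property
    def negative(self) -> bool:
        return self.icc < 0


@dataclass(frozen=True)
class BAResult:
    """Bland-Altman bias and 95% limits of agreement for paired measurements."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def icc(measurements: np.ndarray) -> ICCEstimate:
    """ICC(2,1) from the two-way mean-squares decomposition.

    ``measurements`` is an n x k matrix (subjects x repeated measurements),
    no missing cells, n >= 3 and k >= 2.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2:
        raise ValueError("measurements must be an n x k matrix")
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValueError("need n >= 3 subjects and k >= 2 measurements")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    grand = m.mean()
    if np.allclose(m, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = (msr - mse) / denom
    return ICCEstimate(
        icc=float(value),
        n_subjects=n,
        k_measurements=k,
        var_subject=float((msr - mse) / k),
        var_measurement=float((msc - mse) / n),
        var_error=float(mse),
    )


def bland_altman(pairs: np.ndarray) -> BAResult:
    """Bias and 95% limits of agreement (bias +/- 1.96 sd) of paired data."""
    p = np.asarray(pairs, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("pairs must be an n x 2 matrix")
    if p.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    diffs = p[:, 0] - p[:, 1]
    means = p.mean(axis=1)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BAResult(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, means, diffs)


def feature_pairs_table(pairs, config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Extract features for both members of each (image, mask) pair.

    ``pairs`` is a sequence of ((image, mask), (image, mask)) tuples; the
    result has one row per subject per measurement with a ``measurement``
    column in {1, 2}.
    """
    rows = []
    for sid, ((img1, msk1), (img2, msk2)) in enumerate(pairs):
        for meas, (img, msk) in ((1, (img1, msk1)), (2, (img2, msk2))):
            row = {"subject": sid, "measurement": meas}
            row.update(extract_all(img, msk, config).as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def reliability_report(paired_features: pd.DataFrame,
                       threshold: float = 0.8) -> pd.DataFrame:
    """Per-feature ICC + Bland-Altman from a long-format paired feature table.

    Expects columns ``subject``, ``measurement`` (1/2) and the feature
    columns; returns one row per feature with the robustness flag.
    """
    rows = []
    wide1 = paired_features[paired_features["measurement"] == 1].set_index("subject")
    wide2 = paired_features[paired_features["measurement"] == 2].set_index("subject")
    common = wide1.index.intersection(wide2.index)
    for f in ALL_FEATURE_COLUMNS:
        if f not in paired_features.columns:
            continue
        m = np.column_stack([wide1.loc[common, f], wide2.loc[common, f]])
        if np.allclose(m[:, 0], m[:, 1]) and np.allclose(m, m.mean()):
            est_icc = 1.0  # identical constant measurements agree perfectly
            var_s = var_e = 0.0
        else:
            try:
                est = icc(m)
                est_icc, var_s, var_e = est.icc, est.var_subject, est.var_error
            except ValueError:
                est_icc = 1.0 if np.allclose(m[:, 0], m[:, 1]) else np.nan
                var_s = var_e = np.nan
        ba = bland_altman(m)
        rows.append({
            "feature": f, "icc": est_icc, "robust": bool(est_icc >= threshold),
            "bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high,
            "var_subject": var_s, "var_error": var_e, "n_pairs": len(common),
        })
    return pd.DataFrame(rows)


def reliability_study(pairs, threshold: float = 0.8,
                      config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Full reliability analysis of paired acquisitions/segmentations.

    Runs the extraction pipeline on both members of every pair and reports
    per-feature ICC(2,1), Bland-Altman limits, and the ICC >= threshold
    robustness flag.  Identical pairs give ICC = 1 for every feature.
    """
    table = feature_pairs_table(pairs, config)
    return reliability_report(table, threshold)


def algorithm_pairs(images, init_masks,
                    region_params: ContourParams | None = None,
                    edge_params: ContourParams | None = None):
    """Build between-algorithm pairs: region- vs edge-refined segmentations."""
    region_params = region_params or ContourParams(method="region")
    edge_params = edge_params or ContourParams(method="edge")
    pairs = []
    for img, init in zip(images, init_masks):
        m_region = refine_active_contour(img, init, region_params)
        m_edge = refine_active_contour(img, init, edge_params)
        pairs.append(((img, m_region), (img, m_edge)))
    return pairs
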