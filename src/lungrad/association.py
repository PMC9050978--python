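"""Differential expression of radiomic features against lesion profiles.

Features are tested against binary profiles (five semantic flags, mutant vs
wild-type for EGFR/KRAS/ALK, pairwise histology groups) with the two-sided
Wilcoxon rank-sum test, and against the ordinal histopathological grade with
Spearman's correlation.  Directions are 'up' / 'down' / 'ns' at two
significance tiers (0.05, 0.01); p-values are unadjusted by default, with
optional Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

SEMANTIC_FLAGS = ["solid", "lobular", "spiculated", "juxtapleural", "pleura_tag"]
GENES = ["egfr", "kras", "alk"]
HISTOLOGY_GROUPS = ["adeno", "squamous", "other"]


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    profile: str
    direction: str          # "up" | "down" | "ns"
    p_value: float
    effect: float           # median difference (present minus absent)
    test: str               # "wilcoxon" | "spearman"
    n_group1: int
    n_group0: int

    def __post_init__(self):
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")


def _direction(effect: float, p: float, alpha: float) -> str:
    if p >= alpha or effect == 0:
        return "ns"
    return "up" if effect > 0 else "down"


def wilcoxon_de(values, binary_label, alpha: float = 0.05,
                feature: str = "", profile: str = "") -> AssociationResult:
    """Two-sided Wilcoxon rank-sum comparison of a feature between two groups.

    Exact enumeration when min(n) <= 8 with no ties, otherwise the normal
    approximation with tie and continuity corrections.  Direction is the
    sign of the median difference (label-present minus label-absent) at the
    requested alpha.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(binary_label).astype(int)
    x1, x0 = v[lab == 1], v[lab == 0]
    if x1.size == 0 or x0.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = np.unique(v).size < v.size
    method = "exact" if (min(x1.size, x0.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x1, x0, alternative="two-sided", method=method,
                           use_continuity=True)
    effect = float(np.median(x1) - np.median(x0))
    return AssociationResult(
        feature=feature, profile=profile,
        direction=_direction(effect, res.pvalue, alpha),
        p_value=float(res.pvalue), effect=effect, test="wilcoxon",
        n_group1=int(x1.size), n_group0=int(x0.size),
    )


def spearman_assoc(values, ordinal, alpha: float = 0.05,
                   feature: str = "", profile: str = "grade") -> AssociationResult:
    """Spearman correlation of a feature with an ordinal profile (midrank ties,
    t-approximation p-value, two-sided)."""
    v = np.asarray(values, dtype=float)
    o = np.asarray(ordinal, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(o).size < 2:
        raise ValueError("ordinal profile is constant")
    rho, p = sps.spearmanr(v, o)
    return AssociationResult(
        feature=feature, profile=profile,
        direction=_direction(rho, p, alpha),
        p_value=float(p), effect=float(rho), test="spearman",
        n_group1=int(v.size), n_group0=0,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def association_table(features: pd.DataFrame, profiles: pd.DataFrame,
                      alpha: float = 0.05, adjust: bool = False
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature x profile association screen.

    Returns ``(long, matrix)``: a long-format results table and the
    arrow-matrix pivot whose cells are 'up'/'down'/'ns' plus a star tier
    ('*' for p < 0.05, '**' for p < 0.01).  Binary profiles use Wilcoxon,
    grade uses Spearman; a Kruskal-Wallis omnibus p across the three
    histology groups is reported alongside the pairwise tests.  Missing
    profile columns are skipped with a logged warning.
    """
    feats = [f for f in FEATURE_NAMES + ["diameter_mm"] if f in features.columns]
    results: list[AssociationResult] = []
    extra_rows = []

    def binary_tests(profile_name, label01):
        for f in feats:
            results.append(
                wilcoxon_de(features[f], label01, alpha, feature=f, profile=profile_name)
            )

    for flag in SEMANTIC_FLAGS:
        if flag not in profiles.columns:
            logger.warning("profile column '%s' absent; skipped", flag)
            continue
        binary_tests(flag, profiles[flag].to_numpy())

    for gene in GENES:
        if gene not in profiles.columns:
            logger.warning("profile column '%s' absent; skipped", gene)
            continue
        status = profiles[gene].astype(str)
        known = status.isin(["mutant", "wild"]).to_numpy()
        if status[known].nunique() < 2:
            logger.warning("gene '%s' has a single status; skipped", gene)
            continue
        lab = (status[known] == "mutant").astype(int).to_numpy()
        for f in feats:
            results.append(
                wilcoxon_de(features.loc[known, f], lab, alpha, feature=f, profile=gene)
            )

    if "histology" in profiles.columns:
        hist = profiles["histology"].astype(str)
        groups = [g for g in HISTOLOGY_GROUPS if (hist == g).sum() > 0]
        for a_i in range(len(groups)):
            for b_i in range(a_i + 1, len(groups)):
                a_name, b_name = groups[a_i], groups[b_i]
                sel = hist.isin([a_name, b_name]).to_numpy()
                lab = (hist[sel] == b_name).astype(int).to_numpy()
                for f in feats:
                    results.append(
                        wilcoxon_de(features.loc[sel, f], lab, alpha, feature=f,
                                    profile=f"histology:{b_name}_vs_{a_name}")
                    )
        if len(groups) >= 3:
            for f in feats:
                samples = [features.loc[(hist == g).to_numpy(), f] for g in groups]
                stat, p = sps.kruskal(*samples)
                extra_rows.append({
                    "feature": f, "profile": "histology:omnibus", "direction": "ns",
                    "p_value": float(p), "effect": float(stat), "test": "kruskal",
                    "n_group1": int(sum(len(s) for s in samples)), "n_group0": 0,
                })
    else:
        logger.warning("profile column 'histology' absent; skipped")

    if "grade" in profiles.columns and profiles["grade"].notna().any():
        ok = profiles["grade"].notna().to_numpy()
        for f in feats:
            results.append(
                spearman_assoc(features.loc[ok, f], profiles.loc[ok, "grade"],
                               alpha, feature=f, profile="grade")
            )
    else:
        logger.warning("profile column 'grade' absent; skipped")

    long = pd.DataFrame([r.__dict__ for r in results] + extra_rows)
    if adjust and len(long):
        long["p_value"] = _bh_adjust(long["p_value"].to_numpy())
        long["direction"] = [
            _direction(e, p, alpha) if t != "kruskal" else "ns"
            for e, p, t in zip(long["effect"], long["p_value"], long["test"])
        ]

    def cell(row):
        if row["direction"] == "ns":
            return "ns"
        stars = "**" if row["p_value"] < 0.01 else "*"
        return row["direction"] + stars

    if len(long):
        shown = long[long["test"] != "kruskal"].copy()
        shown["cell"] = shown.apply(cell, axis=1)
        matrix = shown.pivot(index="feature", columns="profile", values="cell")
    else:
        matrix = pd.DataFrame()
    return long, matrix
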