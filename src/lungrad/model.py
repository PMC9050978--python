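"""Composite radiomic score as a model/results pair.

:class:`RadiomicScoreModel` bundles a feature table with survival outcomes;
``fit`` grows the random survival forest and returns
:class:`RadiomicScoreResults`, which carries the fitted forest, the training
scores, and the prognosis analyses (concordance, time-dependent AUC,
median-split stratification with Kaplan-Meier/log-rank, and high-vs-low Cox
hazard ratios, including subgroups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import (
    HRResult,
    auc_t,
    cox_hr_binary,
    harrell_c,
    km_curve,
    logrank_test,
    median_split,
    subgroup_hr,
)
from .features import FEATURE_NAMES
from .forest import (
    RSFHyperParams,
    SurvivalForest,
    fit_rsf,
    normalize_score,
    predict_mortality,
)


class RadiomicScoreModel:
    """Random-survival-forest composite score over the selected features.

    Parameters
    ----------
    features : DataFrame with one row per subject and the predictor columns.
    times, events : survival time in months and the event indicator (0/1).
    feature_names : predictor columns to use (default: the eight selected
        radiomic features present in ``features``).
    hyper : forest hyperparameters (default ntree=50, nodesize=10,
        nodedepth=4, mtry=ceil(sqrt(p))).
    """

    def __init__(self, features: pd.DataFrame, times, events,
                 feature_names: list[str] | None = None,
                 hyper: RSFHyperParams = RSFHyperParams()):
        if feature_names is None:
            feature_names = [f for f in FEATURE_NAMES if f in features.columns]
            if not feature_names:
                raise ValueError("no known feature columns in the table")
        missing = [f for f in feature_names if f not in features.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        self.features = features[feature_names].reset_index(drop=True)
        self.feature_names = feature_names
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=int)
        if (self.times <= 0).any():
            raise ValueError("survival times must be positive")
        if not np.isin(self.events, [0, 1]).all():
            raise ValueError("event flags must be 0/1")
        self.hyper = hyper

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       feature_names: list[str] | None = None,
                       time_col: str = "time_months", event_col: str = "event",
                       hyper: RSFHyperParams = RSFHyperParams()):
        """Build from a single table holding features and outcomes."""
        return cls(df, df[time_col], df[event_col],
                   feature_names=feature_names, hyper=hyper)

    def fit(self) -> "RadiomicScoreResults":
        forest = fit_rsf(self.features, self.times, self.events, self.hyper)
        return RadiomicScoreResults(self, forest)


@dataclass
class EvaluationReport:
    """Prognosis metrics of the score on one cohort."""

    n: int
    n_events: int
    concordance: float
    auc: dict[float, float]             # horizon (months) -> AUCt
    hr: HRResult | None
    logrank_chi2: float | None
    logrank_p: float | None


class RadiomicScoreResults:
    """Fitted composite score with its prognosis analyses."""

    def __init__(self, model: RadiomicScoreModel, forest: SurvivalForest):
        self.model = model
        self.forest = forest
        self.train_scores = self.predict_scores(model.features)

    def predict_scores(self, features: pd.DataFrame) -> np.ndarray:
        """0-100 composite score for new subjects (training normalization)."""
        risk = predict_mortality(self.forest, features)
        return normalize_score(self.forest, risk)

    def evaluate(self, features: pd.DataFrame, times, events,
                 horizons=(24.0, 60.0)) -> EvaluationReport:
        """Concordance, AUCt at the requested horizons, and the median-split
        stratification (log-rank + Cox HR) on an arbitrary cohort."""
        scores = self.predict_scores(features)
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=int)
        c = harrell_c(scores, t, e)
        aucs = {}
        for h in horizons:
            try:
                aucs[float(h)] = auc_t(scores, t, e, float(h))
            except ValueError:
                aucs[float(h)] = float("nan")
        hr = chi2 = p = None
        try:
            labels = median_split(scores)
            hi, lo = labels == "high", labels == "low"
            chi2, p = logrank_test(t[lo], e[lo], t[hi], e[hi])
            hr = cox_hr_binary(labels, t, e)
        except ValueError:
            pass
        return EvaluationReport(
            n=len(t), n_events=int(e.sum()), concordance=c, auc=aucs,
            hr=hr, logrank_chi2=chi2, logrank_p=p,
        )

    def stratify(self, features: pd.DataFrame, times, events):
        """Median-split groups with their Kaplan-Meier curves."""
        scores = self.predict_scores(features)
        labels = median_split(scores)
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=int)
        lo, hi = labels == "low", labels == "high"
        return {
            "labels": labels,
            "km_low": km_curve(t[lo], e[lo]),
            "km_high": km_curve(t[hi], e[hi]),
        }

    def subgroup_table(self, features: pd.DataFrame, times, events,
                       subgroups: dict[str, np.ndarray]) -> pd.DataFrame:
        scores = self.predict_scores(features)
        return subgroup_hr(scores, times, events, subgroups)

    def summary(self, horizons=(24.0, 60.0)) -> str:
        """Plain-text summary of the fit and the training-cohort metrics."""
        rep = self.evaluate(self.model.features, self.model.times,
                            self.model.events, horizons)
        h = self.forest.hyper
        lines = [
            "Composite radiomic score (random survival forest)",
            "=" * 50,
            f"subjects: {rep.n}   events: {rep.n_events}",
            f"features: {', '.join(self.model.feature_names)}",
            f"hyperparameters: ntree={h.ntree} nodesize={h.nodesize} "
            f"nodedepth={h.nodedepth} mtry={h.mtry or 'ceil(sqrt(p))'} seed={h.seed}",
            f"training C-statistic: {rep.concordance:.3f}",
        ]
        for hz, a in rep.auc.items():
            lines.append(f"AUC at {hz:.0f} months: {a:.3f}")
        if rep.hr is not None:
            lines.append(
                f"high vs low score HR: {rep.hr.hr:.3f} "
                f"(95% CI {rep.hr.ci_low:.3f}-{rep.hr.ci_high:.3f}), "
                f"log-rank p = {rep.logrank_p:.4f}"
            )
        return "\n".join(lines)
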