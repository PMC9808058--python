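"""Survival-gene screening, linear risk score, and stratified survival tests.

The stage chain mirrors a standard prognostic-signature workflow:

* screen genes for association with overall survival by median-split of
  each gene's expression followed by a two-group log-rank test;
* combine a set of signature genes into a linear risk score
  ``score_s = sum_i coef_i * expr_{i,s}`` (coefficients are inputs, e.g.
  from a penalized Cox fit done elsewhere);
* dichotomize samples at the median risk score (ties go to "low");
* compare the two arms with Kaplan–Meier curves and the log-rank test;
* screen auxiliary features (e.g. lncRNA expression) against the risk
  score with a tie-corrected Spearman test (|rho| > 0.3 and p < 0.05 by
  default, both strict).

Kaplan–Meier and log-rank computations are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalData",
    "RiskModel",
    "KMCurve",
    "LogrankResult",
    "read_expression",
    "read_survival",
    "read_risk_model",
    "screen_survival_genes",
    "risk_score",
    "dichotomize_by_median",
    "km_estimate",
    "logrank_test",
    "spearman_screen",
    "MedianSplitLogrankScreen",
    "RiskScorer",
    "SpearmanScreen",
]


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored time-to-event records (time > 0; event 1=observed, 0=censored)."""

    frame: pd.DataFrame  # index sample_id; columns time, event

    def __post_init__(self) -> None:
        missing = {"time", "event"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"survival table lacks columns: {sorted(missing)}")
        if (self.frame["time"] <= 0).any():
            bad = self.frame.index[self.frame["time"] <= 0].tolist()
            raise ValueError(f"non-positive survival time for samples: {bad[:5]}")
        if not self.frame["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def time(self) -> pd.Series:
        return self.frame["time"]

    @property
    def event(self) -> pd.Series:
        return self.frame["event"]

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalData":
        return SurvivalData(self.frame.loc[list(sample_ids)])


@dataclass(frozen=True)
class RiskModel:
    """Signature genes with signed coefficients for the linear risk score."""

    coefficients: pd.Series  # index gene_id

    def __post_init__(self) -> None:
        if len(self.coefficients) < 1:
            raise ValueError("a risk model needs at least one gene")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.coefficients.index)

    @property
    def n_genes(self) -> int:
        return len(self.coefficients)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate at the distinct observed event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        s = self.survival
        if s.size and (np.any(s < -1e-12) or np.any(s > 1 + 1e-12) or np.any(np.diff(s) > 1e-12)):
            raise ValueError("survival probabilities must be non-increasing within [0, 1]")

    def survival_at(self, times) -> np.ndarray:
        """Step-function S(t); S = 1 before the first event time."""
        idx = np.searchsorted(self.event_times, np.atleast_1d(times), side="right")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times, "at_risk": self.at_risk,
            "events": self.events, "survival": self.survival,
        })


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    group_sizes: dict[str, int]


# ---------------------------------------------------------------------------
# TSV loaders (thin pandas wrappers; formats documented in the CLI help)
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples expression TSV (first column gene id)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.isna().any().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    return expr


def read_survival(path: str | Path) -> SurvivalData:
    """Survival TSV with columns sample, time, event."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SurvivalData(frame[["time", "event"]])


def read_risk_model(path: str | Path) -> RiskModel:
    """Model TSV with columns gene, coefficient."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return RiskModel(frame["coefficient"].astype(float))


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def km_estimate(surv: SurvivalData) -> KMCurve:
    """Kaplan–Meier product-limit estimator S(t) = prod (1 - d_j/n_j)."""
    if len(surv.frame) < 1:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, event_observed=surv.event)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv_prob = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(event_times=times,
                   at_risk=ev["at_risk"].to_numpy(dtype=int),
                   events=ev["observed"].to_numpy(dtype=int),
                   survival=surv_prob)


def logrank_test(surv: SurvivalData, groups: Mapping[str, str] | pd.Series) -> LogrankResult:
    """Two-group log-rank test (O-E over pooled event times, 1-df chi-square)."""
    groups = pd.Series(groups)
    frame = surv.frame.join(groups.rename("group"), how="inner")
    names = sorted(frame["group"].unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {names}")
    a = frame[frame["group"] == names[0]]
    b = frame[frame["group"] == names[1]]
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    if int(frame["event"].sum()) < 1:
        raise ValueError("need at least one observed event")
    res = _ll_logrank(a["time"], b["time"],
                      event_observed_A=a["event"], event_observed_B=b["event"])
    return LogrankResult(statistic=float(res.test_statistic), p_value=float(res.p_value),
                         group_sizes={names[0]: len(a), names[1]: len(b)})


def _median_split(values: pd.Series) -> pd.Series:
    median = values.median()
    return pd.Series(np.where(values > median, "high", "low"), index=values.index)


def dichotomize_by_median(scores: Mapping[str, float] | pd.Series) -> pd.Series:
    """Split samples at the median score; ties (score == median) go to "low"."""
    scores = pd.Series(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least 2 samples")
    if scores.nunique() == 1:
        raise ValueError("no variation: all risk scores identical")
    return _median_split(scores)


def screen_survival_genes(expr: pd.DataFrame, surv: SurvivalData,
                          alpha: float = 0.05,
                          correction: str = "none") -> pd.DataFrame:
    """Median-split log-rank screen of every gene against survival.

    Returns a DataFrame indexed by gene with columns ``p_value``,
    ``p_adjusted`` (Benjamini–Hochberg when ``correction="BH"``) and
    ``selected``.  Genes whose median split leaves fewer than 2 samples in
    an arm (constant genes in particular) are excluded with a warning.
    """
    if correction not in ("none", "BH"):
        raise ValueError(f"correction must be 'none' or 'BH', got {correction!r}")
    common = [s for s in expr.columns if s in surv.frame.index]
    if len(common) < 4:
        raise ValueError("need >=4 samples shared between expression and survival")
    surv = surv.subset(common)
    records = {}
    for gene, values in expr[common].iterrows():
        groups = _median_split(values)
        sizes = groups.value_counts()
        if len(sizes) < 2 or sizes.min() < 2:
            logger.warning("screen: gene %s cannot be median-split (constant or near-constant), excluded", gene)
            continue
        res = logrank_test(surv, groups)
        records[gene] = res.p_value
    out = pd.DataFrame({"p_value": pd.Series(records, dtype=float)})
    out.index.name = "gene"
    if correction == "BH" and len(out):
        out["p_adjusted"] = stats.false_discovery_control(out["p_value"], method="bh")
    else:
        out["p_adjusted"] = out["p_value"]
    out["selected"] = out["p_adjusted"] < alpha
    return out


def risk_score(expr: pd.DataFrame, model: RiskModel) -> pd.Series:
    """Linear risk score per sample: sum_i coef_i * expr_{i, s}."""
    missing = [g for g in model.gene_ids if g not in expr.index]
    if missing:
        raise KeyError(f"model genes absent from the expression matrix: {missing}")
    scores = model.coefficients @ expr.loc[model.gene_ids]
    scores.name = "risk_score"
    return scores


def spearman_screen(scores: pd.Series, features: pd.DataFrame,
                    r_min: float = 0.3, alpha: float = 0.05) -> pd.DataFrame:
    """Screen features (rows) against the risk score by Spearman correlation.

    Tie-corrected rho with the t-approximation p-value (n-2 df); a feature
    passes when |rho| > ``r_min`` and p < ``alpha`` (both strict).  Constant
    features are skipped with a warning.
    """
    common = [s for s in features.columns if s in scores.index]
    if len(common) < 4:
        raise ValueError("need >=4 paired observations")
    aligned_scores = scores[common].to_numpy(dtype=float)
    records = {}
    for feature, values in features[common].iterrows():
        v = values.to_numpy(dtype=float)
        if np.all(v == v[0]):
            logger.warning("spearman screen: feature %s is constant, skipped", feature)
            continue
        rho, p = stats.spearmanr(aligned_scores, v)
        records[feature] = (rho, p)
    out = pd.DataFrame.from_dict(records, orient="index", columns=["rho", "p_value"])
    out.index.name = "feature"
    out["selected"] = (out["rho"].abs() > r_min) & (out["p_value"] < alpha)
    return out


# ---------------------------------------------------------------------------
# estimator wrappers
# ---------------------------------------------------------------------------

class MedianSplitLogrankScreen(BaseEstimator):
    """Feature selector: keep genes whose median split stratifies survival.

    ``X`` is samples x genes (scikit-learn orientation, a DataFrame);
    ``y`` is a :class:`SurvivalData` (or a time/event DataFrame).
    """

    def __init__(self, alpha: float = 0.05, correction: str = "none"):
        self.alpha = alpha
        self.correction = correction

    def fit(self, X: pd.DataFrame, y) -> "MedianSplitLogrankScreen":
        surv = y if isinstance(y, SurvivalData) else SurvivalData(y)
        report = screen_survival_genes(X.T, surv, alpha=self.alpha, correction=self.correction)
        self.report_ = report
        self.pvalues_ = report["p_value"]
        self.selected_genes_ = list(report.index[report["selected"]])
        self.support_ = np.array([g in set(self.selected_genes_) for g in X.columns])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, X.columns[self.support_]]

    def fit_transform(self, X: pd.DataFrame, y) -> pd.DataFrame:
        return self.fit(X, y).transform(X)

    def get_support(self) -> np.ndarray:
        return self.support_


class RiskScorer(BaseEstimator):
    """Linear risk-score predictor with median dichotomization.

    ``fit`` records the training-cohort median; ``predict`` returns scores
    and ``predict_group`` the high/low arm relative to that median.
    """

    def __init__(self, coefficients: Mapping[str, float] | pd.Series | RiskModel = None):
        self.coefficients = coefficients

    def _model(self) -> RiskModel:
        if isinstance(self.coefficients, RiskModel):
            return self.coefficients
        return RiskModel(pd.Series(self.coefficients, dtype=float))

    def fit(self, X: pd.DataFrame, y=None) -> "RiskScorer":
        scores = risk_score(X.T, self._model())
        self.median_ = float(scores.median())
        self.training_scores_ = scores
        self.training_groups_ = dichotomize_by_median(scores)
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        return risk_score(X.T, self._model())

    def predict_group(self, X: pd.DataFrame) -> pd.Series:
        scores = self.predict(X)
        return pd.Series(np.where(scores > self.median_, "high", "low"), index=scores.index)


class SpearmanScreen(BaseEstimator):
    """Feature selector on |Spearman rho| and p-value against a score vector."""

    def __init__(self, r_min: float = 0.3, alpha: float = 0.05):
        self.r_min = r_min
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "SpearmanScreen":
        report = spearman_screen(pd.Series(y), X.T, r_min=self.r_min, alpha=self.alpha)
        self.report_ = report
        self.selected_features_ = list(report.index[report["selected"]])
        self.support_ = np.array([f in set(self.selected_features_) for f in X.columns])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, X.columns[self.support_]]

    def get_support(self) -> np.ndarray:
        return self.support_
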