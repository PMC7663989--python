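"""Model-performance statistics: confusion matrices, omission/commission
error rates, Cohen's kappa, regression fit statistics, and binned
Kolmogorov-Smirnov goodness-of-fit tests.

Kappa follows the standard chance-corrected agreement definition
K = (Po - Pe) / (1 - Pe) with Pe from the row/column marginals; K > 0.6
is conventionally read as substantial agreement. Omission is the rate of
observed presences predicted absent (false negatives over observed
presences); commission is the rate of observed absences predicted
present. The binned K-S statistic is the maximum absolute difference of
cumulative relative frequencies, with the asymptotic 5% critical value
1.36 / sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "KsResult", "confusion", "kappa",
           "per_class_kappa", "error_rates", "fit_stats", "ks_test"]


@dataclass
class ConfusionMatrix:
    """Cross-tabulation of observed (rows) against predicted (columns)."""

    counts: np.ndarray
    labels: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.labels, name="observed")
        cols = pd.Index(self.labels, name="predicted")
        return pd.DataFrame(self.counts, index=idx, columns=cols)

    def presence_absence(self, presence_from: int = 1) -> "ConfusionMatrix":
        """Collapse class codes >= ``presence_from`` into 'present'."""
        codes = np.asarray([int(c) for c in np.arange(len(self.labels))])
        present = codes >= presence_from
        out = np.zeros((2, 2), dtype=np.int64)
        for i in range(len(self.labels)):
            for j in range(len(self.labels)):
                out[int(present[i]), int(present[j])] += self.counts[i, j]
        return ConfusionMatrix(out, ["absent", "present"])


def confusion(observed, predicted, labels=None) -> ConfusionMatrix:
    """Cross-tabulate observed vs predicted class codes."""
    obs = np.asarray(observed, dtype=int)
    pred = np.asarray(predicted, dtype=int)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    if labels is None:
        labels = list(range(max(obs.max(), pred.max()) + 1))
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (obs, pred), 1)
    return ConfusionMatrix(counts, list(labels))


def _as_counts(matrix) -> np.ndarray:
    if isinstance(matrix, ConfusionMatrix):
        return matrix.counts
    return np.asarray(matrix, dtype=np.int64)


def kappa(matrix) -> float:
    """Cohen's kappa of a (square) confusion matrix.

    Raises on degenerate marginals (expected agreement of exactly 1,
    e.g. all mass in one observed and one predicted category).
    """
    counts = _as_counts(matrix)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(counts) / total
    pe = float((counts.sum(axis=1) / total) @ (counts.sum(axis=0) / total))
    if pe >= 1.0:
        raise ZeroDivisionError("kappa undefined: chance agreement is 1")
    return float((po - pe) / (1.0 - pe))


def per_class_kappa(matrix: ConfusionMatrix) -> pd.Series:
    """One-vs-rest kappa per class (class c vs all others collapsed)."""
    counts = matrix.counts
    k = counts.shape[0]
    out = {}
    for c in range(k):
        tp = counts[c, c]
        fn = counts[c].sum() - tp
        fp = counts[:, c].sum() - tp
        tn = counts.sum() - tp - fn - fp
        out[matrix.labels[c]] = kappa(np.array([[tn, fp], [fn, tp]]))
    return pd.Series(out, name="kappa")


def error_rates(matrix) -> dict:
    """Omission/commission rates, prevalence, and percent correct.

    For a 2x2 presence-absence matrix (rows observed [absent, present]):
    omission = FN / observed present, commission = FP / observed absent,
    prevalence = observed present / total. Percent correct (trace/total)
    is reported for any square matrix. Rates whose observed class is
    empty come back as NaN.
    """
    counts = _as_counts(matrix)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    out = {"percent_correct": float(np.trace(counts) / total)}
    if counts.shape == (2, 2):
        (tn, fp), (fn, tp) = counts
        n_abs, n_pres = tn + fp, fn + tp
        out["omission"] = float(fn / n_pres) if n_pres else np.nan
        out["commission"] = float(fp / n_abs) if n_abs else np.nan
        out["prevalence"] = float(n_pres / total)
        out["sensitivity"] = float(tp / n_pres) if n_pres else np.nan
        out["specificity"] = float(tn / n_abs) if n_abs else np.nan
    return out


def fit_stats(observed, predicted, n_predictors: int) -> dict:
    """R^2, adjusted R^2 and MSE of continuous predictions.

    R^2 = 1 - SSE/SST; adjusted for ``n_predictors`` model inputs;
    MSE = SSE / n. Observed values with zero variance are rejected.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = len(obs)
    if n != len(pred):
        raise ValueError("length mismatch")
    if n <= n_predictors + 1:
        raise ValueError("need n > n_predictors + 1")
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    sse = float(((obs - pred) ** 2).sum())
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)
    return {"r2": r2, "r2_adj": r2_adj, "mse": sse / n}


@dataclass
class KsResult:
    """Binned K-S statistic with its asymptotic critical value."""

    d: float
    critical_d: float
    n: int
    alpha: float

    def __post_init__(self):
        if not 0 <= self.d <= 1:
            raise ValueError("D must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        """True when the observed distribution differs from the expected
        one at level alpha (D exceeds the critical value)."""
        return self.d > self.critical_d


def ks_test(observed_counts, expected_freqs, n: int | None = None,
            alpha: float = 0.05) -> KsResult:
    """Binned K-S goodness-of-fit of observed counts to expected relative
    frequencies over ordered bins.

    D is the maximum absolute difference between the cumulative observed
    and expected relative frequencies. ``n`` is the sample count used for
    the critical value 1.36/sqrt(n); it defaults to the observed total
    but can be supplied separately when the tallies are fish counts while
    the sampling unit is the collection.
    """
    obs = np.asarray(observed_counts, dtype=float)
    exp = np.asarray(expected_freqs, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must align bin-for-bin")
    if obs.sum() <= 0:
        raise ValueError("no observed counts")
    if not np.isclose(exp.sum(), 1.0, atol=1e-6):
        raise ValueError("expected frequencies must sum to 1")
    cum_obs = np.cumsum(obs / obs.sum())
    cum_exp = np.cumsum(exp)
    d = float(np.abs(cum_obs - cum_exp).max())
    if n is None:
        n = int(obs.sum())
    if n <= 0:
        raise ValueError("n must be positive")
    return KsResult(d=d, critical_d=1.36 / np.sqrt(n), n=n, alpha=alpha)
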