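"""Statistical layer: Friedman tests, Wilcoxon, chi-square criticals and
leave-one-out linear-discriminant classification.

The Friedman test in two-way layout with replicated cells follows the
classical rank procedure: within each block the ``treatments x replicates``
observations are ranked jointly (midranks on ties); with ``R_j`` the total
rank sum of treatment j over n blocks, c replicates, m = k*c ranks per
block and per-block rank variance ``s2_b = mean((r - (m+1)/2)^2)``, the
statistic is::

    chi2 = sum_j (R_j - n c (m+1)/2)^2  /  sum_b [ c m s2_b / (m-1) ]

with k-1 degrees of freedom.  For c = 1 and no ties this reduces to the
textbook ``12 / (n k (k+1)) * sum_j (R_j - n(k+1)/2)^2``, and the
denominator reproduces the standard tie correction exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FriedmanResult",
    "ClassificationResult",
    "friedman_blocked",
    "friedman_repeated",
    "chi2_critical",
    "wilcoxon_signed_rank",
    "lda_loo",
    "normalize_per_muscle",
]


@dataclass
class FriedmanResult:
    chi2: float
    dof: int
    p: float
    alpha: float
    significant: bool
    n_comparisons: int = 1  # Bonferroni family size


@dataclass
class ClassificationResult:
    """Leave-one-out confusion matrix with micro-averaged indexes.

    Micro counts pool per-class one-vs-rest TP/FP/TN/FN: correctly
    classified samples count as TP of their class, misclassified ones as
    FN of the true class and FP of the predicted class.
    """

    classes: list
    confusion: np.ndarray  # rows = true, cols = predicted

    @property
    def n_samples(self) -> int:
        return int(self.confusion.sum())

    @property
    def micro_counts(self) -> tuple[int, int, int, int]:
        conf = self.confusion
        total = conf.sum()
        diag = np.diag(conf)
        tp = int(diag.sum())
        fp = int((conf.sum(axis=0) - diag).sum())
        fn = int((conf.sum(axis=1) - diag).sum())
        # one-vs-rest TN per class: total - row - col + diag; summed
        tn = int(sum(total - conf[i].sum() - conf[:, i].sum() + conf[i, i]
                     for i in range(len(self.classes))))
        return tp, fp, tn, fn

    def _ratio(self, num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    @property
    def accuracy(self) -> float:
        return self._ratio(int(np.trace(self.confusion)), self.n_samples)

    @property
    def sensitivity(self) -> float:
        tp, fp, tn, fn = self.micro_counts
        return self._ratio(tp, tp + fn)

    @property
    def specificity(self) -> float:
        tp, fp, tn, fn = self.micro_counts
        return self._ratio(tn, tn + fp)

    @property
    def precision(self) -> float:
        tp, fp, tn, fn = self.micro_counts
        return self._ratio(tp, tp + fp)


def friedman_blocked(
    data: np.ndarray,
    replication: int = 1,
    alpha: float = 0.05,
) -> FriedmanResult:
    """Friedman test for a blocks x treatments layout with replicated cells.

    ``data`` has shape ``(n_blocks * replication, n_treatments)``; each
    consecutive group of ``replication`` rows is one block (the layout used
    by the classical replicated two-way rank procedure).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (blocks*replication x treatments)")
    if np.isnan(data).any():
        raise ValueError("incomplete design: missing cells")
    rows, k = data.shape
    if k < 2:
        raise ValueError("need >= 2 treatments")
    if replication < 1 or rows % replication != 0:
        raise ValueError("row count is not a multiple of the replication factor")
    n = rows // replication
    if n < 2:
        raise ValueError("need >= 2 blocks")
    c = replication
    m = k * c
    rank_sums = np.zeros(k)
    denom = 0.0
    centre = (m + 1) / 2.0
    for b in range(n):
        block = data[b * c : (b + 1) * c, :]  # c x k
        ranks = sps.rankdata(block, axis=None).reshape(c, k)
        rank_sums += ranks.sum(axis=0)
        s2 = ((ranks - centre) ** 2).mean()
        denom += c * m * s2 / (m - 1)
    expected = n * c * centre
    num = ((rank_sums - expected) ** 2).sum()
    chi2 = num / denom if denom > 0 else 0.0
    dof = k - 1
    p = float(sps.chi2.sf(chi2, dof)) if denom > 0 else 1.0
    return FriedmanResult(float(chi2), dof, p, alpha, p < alpha)


def friedman_repeated(
    measures: np.ndarray,
    alpha: float = 0.05,
    bonferroni: int | None = None,
) -> FriedmanResult:
    """Repeated-measures Friedman over subjects x conditions with a
    Bonferroni-corrected significance level (family size defaults to the
    number of conditions, e.g. 12 = 4 tasks x 3 efforts)."""
    measures = np.asarray(measures, dtype=float)
    if measures.ndim != 2:
        raise ValueError("measures must be subjects x conditions")
    if np.isnan(measures).any():
        raise ValueError("incomplete design: missing measures")
    n_cond = measures.shape[1]
    family = bonferroni if bonferroni is not None else n_cond
    res = friedman_blocked(measures, replication=1, alpha=alpha / family)
    res.n_comparisons = family
    res.significant = res.chi2 > chi2_critical(res.dof, alpha / family)
    return res


def chi2_critical(dof: int, alpha: float) -> float:
    """Upper-tail critical value of the chi-square distribution."""
    if dof < 1:
        raise ValueError("dof must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return float(sps.chi2.isf(alpha, dof))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; ties get midranks.  Raises ``ValueError``
    when every difference is zero (degenerate test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        raise ValueError("degenerate test: all paired differences are zero")
    res = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def lda_loo(X: np.ndarray, y: np.ndarray) -> ClassificationResult:
    """Leave-one-out linear discriminant classification with uniform priors.

    Each sample is predicted by an LDA fitted on all remaining samples
    (pooled within-class covariance; the SVD solver handles near-singular
    covariances without explicit inversion).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_features) matching y")
    classes = sorted(set(y.tolist()))
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("need >= 2 samples per class for leave-one-out")
    if X.shape[1] >= X.shape[0] - 1:
        raise ValueError("feature count must be < sample count - 1")
    idx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    priors = np.full(len(classes), 1.0 / len(classes))
    n = X.shape[0]
    for i in range(n):
        keep = np.arange(n) != i
        clf = LinearDiscriminantAnalysis(solver="svd", priors=priors)
        clf.fit(X[keep], y[keep])
        pred = clf.predict(X[i : i + 1])[0]
        conf[idx[y[i]], idx[pred]] += 1
    return ClassificationResult(classes=classes, confusion=conf)


def normalize_per_muscle(
    table: pd.DataFrame,
    feature_cols: tuple[str, ...] = ("rms_av_hd", "rms_av_bip"),
    muscle_col: str = "muscle",
) -> pd.DataFrame:
    """Divide each muscle's feature values by that muscle's grand mean over
    all tasks and contraction levels (removes recording-type scale)."""
    out = table.copy()
    for col in feature_cols:
        means = table.groupby(muscle_col)[col].transform("mean")
        if (means == 0).any():
            raise ValueError(f"zero grand mean in column {col!r}")
        out[col] = table[col] / means
    return out
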