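"""Feature normalisation, weighted-LASSO ranking and quadruple search.

Selection proceeds in three steps:

1. per-feature contrast stretching between the 2.5th and 97.5th percentiles
   followed by z-scoring (parameters stored for reuse on held-out data);
2. LASSO ranking with 3-fold cross-validated penalty, each observation
   weighted inversely to its class frequency; features with a non-zero
   coefficient at the minimum-CV-error penalty are retained, ranked by
   |coefficient|;
3. exhaustive search over all 4-subsets of the retained features:
   combinations containing any pair with Spearman |rho| > 0.3 are discarded,
   the survivors are scored by the worst (largest) of their four per-feature
   Wilcoxon rank-sum p-values, Holm–Bonferroni corrected across survivors at
   alpha = 1e-3, and the lowest-scoring significant quadruple wins (ties
   break by enumeration order).

The rank-sum test is univariate; scoring a combination by its worst member
is this package's choice of combination-level statistic and is recorded in
every result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

SCORE_RULE = "max of the four member-wise Wilcoxon rank-sum p-values"


class NoSignatureError(RuntimeError):
    """No quadruple survives correlation filtering + Holm–Bonferroni."""


@dataclass
class NormalizationParams:
    """Per-feature contrast-stretch percentiles and post-stretch moments."""

    p_lo: pd.Series
    p_hi: pd.Series
    mean_: pd.Series
    sd_: pd.Series
    median_: pd.Series            # train medians, used to impute missing
    kept: list[str] = field(default_factory=list)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X[self.kept].copy()
        X = X.fillna(self.median_)
        stretched = (X.clip(self.p_lo, self.p_hi, axis=1) - self.p_lo) \
            / (self.p_hi - self.p_lo)
        return (stretched - self.mean_) / self.sd_


def normalize_standardize(X: pd.DataFrame):
    """Contrast-stretch each feature to [0, 1] (2.5–97.5 pct) then z-score.

    Zero-variance features (after stretching) are dropped with a warning.
    Missing entries are imputed with the feature median before stretching.
    Returns the transformed matrix and the fitted parameters.
    """
    if len(X) < 8:
        raise ValueError("need >= 8 samples to estimate percentiles")
    X = X.copy()
    median_ = X.median()
    X = X.fillna(median_)
    p_lo = X.quantile(0.025)
    p_hi = X.quantile(0.975)
    span = p_hi - p_lo
    kept = list(X.columns[span > 0])
    dropped = [c for c in X.columns if c not in kept]
    if dropped:
        logger.warning("normalize_standardize: dropping %d zero-variance "
                       "features", len(dropped))
    X = X[kept]
    p_lo, p_hi = p_lo[kept], p_hi[kept]
    stretched = (X.clip(p_lo, p_hi, axis=1) - p_lo) / (p_hi - p_lo)
    mean_ = stretched.mean()
    sd_ = stretched.std(ddof=0)
    ok = sd_ > 0
    if not ok.all():
        logger.warning("normalize_standardize: dropping %d constant features "
                       "post-stretch", int((~ok).sum()))
        kept = list(np.array(kept)[ok.to_numpy()])
        stretched = stretched[kept]
        p_lo, p_hi, mean_, sd_ = p_lo[kept], p_hi[kept], mean_[kept], sd_[kept]
    Xn = (stretched - mean_) / sd_
    params = NormalizationParams(p_lo, p_hi, mean_, sd_, median_[kept], kept)
    return Xn, params


@dataclass
class LassoRanking:
    alpha: float
    coefficients: pd.Series
    retained: list[str]           # non-zero coefficients, ranked by |coef|

    def top(self, n: int) -> list[str]:
        return self.retained[:n]


def lasso_rank(Xn: pd.DataFrame, y: np.ndarray, folds: int = 3,
               seed: int = 0, n_alphas: int = 100) -> LassoRanking:
    """Class-balanced LASSO ranking at the minimum-CV-error penalty.

    Observations are weighted with ``n / (2 * n_class)`` so both classes
    contribute equally to the squared-error objective.
    """
    y = np.asarray(y, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("y must contain exactly two classes")
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} samples per class")
    weights = np.empty(len(y))
    for cls, cnt in zip(classes, counts):
        weights[y == cls] = len(y) / (2.0 * cnt)

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, alphas=n_alphas, max_iter=50000, random_state=seed)
    model.fit(Xn.to_numpy(), y, sample_weight=weights)
    coef = pd.Series(model.coef_, index=Xn.columns)
    nz = coef[coef != 0.0]
    retained = list(nz.reindex(nz.abs().sort_values(ascending=False).index).index)
    return LassoRanking(float(model.alpha_), coef, retained)


def enumerate_quadruples(feature_set) -> list[tuple]:
    """All C(n, 4) four-subsets in deterministic lexicographic order."""
    feature_set = list(feature_set)
    if len(feature_set) < 4:
        raise ValueError("need at least 4 features")
    return list(combinations(feature_set, 4))


@dataclass
class QuadrupleResult:
    features: tuple
    p_value: float                 # worst member-wise rank-sum p
    p_adjusted: float              # Holm-adjusted
    significant: bool
    n_quadruples: int
    n_discarded_correlated: int
    n_tested: int
    score_rule: str = SCORE_RULE


def _pair_correlation(Xn: pd.DataFrame, y: np.ndarray, names: list,
                      corr_method: str, corr_scope: str) -> pd.DataFrame:
    """|correlation| between features, pooled or within class.

    ``"within"`` takes, per pair, the larger of the two class-conditional
    |rho| values: it measures redundancy between features beyond what the
    class label itself induces, so that two independent markers that both
    separate the classes strongly are not flagged as a correlated couple.
    ``"pooled"`` is the plain sample correlation.
    """
    if corr_scope == "pooled":
        return Xn[names].corr(method=corr_method).abs()
    if corr_scope != "within":
        raise ValueError(f"unknown corr_scope {corr_scope!r}")
    per_class = [Xn[names][y == cls].corr(method=corr_method).abs()
                 for cls in np.unique(y)]
    out = per_class[0]
    for c in per_class[1:]:
        out = out.combine(c, func=np.maximum)
    return out


def _score_quadruples(quadruples, Xn: pd.DataFrame, y: np.ndarray,
                      rho_max: float, corr_method: str,
                      corr_scope: str = "within"):
    """Correlation filter + worst-member rank-sum score per surviving quad."""
    quadruples = list(quadruples)
    y = np.asarray(y)
    names = {n for q in quadruples for n in q}
    corr = _pair_correlation(Xn, y, sorted(names), corr_method, corr_scope)
    pos, neg = Xn[y == 1], Xn[y == 0]
    p_feature = {
        n: stats.ranksums(pos[n].to_numpy(), neg[n].to_numpy()).pvalue
        for n in names
    }
    survivors, scores = [], []
    n_corr = 0
    for quad in quadruples:
        if any(corr.loc[a, b] > rho_max for a, b in combinations(quad, 2)):
            n_corr += 1
            continue
        survivors.append(quad)
        scores.append(max(p_feature[n] for n in quad))
    return quadruples, survivors, np.asarray(scores), n_corr


def filter_and_test(quadruples, Xn: pd.DataFrame, y: np.ndarray,
                    rho_max: float = 0.3, alpha: float = 1e-3,
                    corr_method: str = "spearman",
                    corr_scope: str = "within") -> QuadrupleResult:
    """Correlation-filter the quadruples and pick the most discriminant one.

    Raises :class:`NoSignatureError` if nothing survives the Holm–Bonferroni
    correction at ``alpha``.
    """
    quadruples, survivors, scores, n_corr = _score_quadruples(
        quadruples, Xn, y, rho_max, corr_method, corr_scope)
    if not survivors:
        raise NoSignatureError(
            "all quadruples discarded by the correlation filter")
    reject, p_adj, _, _ = multipletests(scores, alpha=alpha, method="holm")
    if not reject.any():
        raise NoSignatureError(
            "no quadruple significant after Holm–Bonferroni correction")
    cand = np.flatnonzero(reject)
    best = cand[np.argmin(scores[cand])]   # argmin keeps enumeration order on ties
    return QuadrupleResult(
        features=tuple(survivors[best]),
        p_value=float(scores[best]),
        p_adjusted=float(p_adj[best]),
        significant=True,
        n_quadruples=len(quadruples),
        n_discarded_correlated=n_corr,
        n_tested=len(survivors),
    )


def best_quadruple_unchecked(quadruples, Xn, y, rho_max=0.3,
                             corr_method="spearman",
                             corr_scope="within") -> QuadrupleResult:
    """Lowest-score quadruple regardless of significance.

    Fallback used by the pipeline so that null cohorts (e.g. permuted
    labels) still complete end to end; the result is flagged
    ``significant=False`` unless Holm–Bonferroni at 1e-3 would accept it.
    If the correlation filter removes everything, it is ignored.
    """
    quadruples, survivors, scores, n_corr = _score_quadruples(
        quadruples, Xn, y, rho_max, corr_method, corr_scope)
    if not survivors:
        logger.warning("quadruple fallback: correlation filter removed all "
                       "combinations; ignoring it")
        quadruples, survivors, scores, n_corr = _score_quadruples(
            quadruples, Xn, y, np.inf, corr_method, corr_scope)
    reject, p_adj, _, _ = multipletests(scores, alpha=1e-3, method="holm")
    best = int(np.argmin(scores))
    return QuadrupleResult(tuple(survivors[best]), float(scores[best]),
                           float(p_adj[best]), bool(reject[best]),
                           len(quadruples), n_corr, len(survivors))
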