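"""Clinical performance metrics: ROC/AUC, predictive values, calibration, DCA.

Definitions (MVI+ = positive):

* SN = TP/(TP+FN), SP = TN/(TN+FP), informedness I = SN + SP - 1;
* PPV = TP/(TP+FP), NPV = TN/(TN+FN), predictive summary index
  PSI = PPV + NPV - 1;
* predictive ratios PPR = PPV/(1-NPV) and NPR = (1-PPV)/NPV (how many times
  more often a positive/negative call is right than wrong relative to the
  opposite call);
* Youden cut-off: score threshold maximising SN + SP - 1 (lowest on ties);
* decision-curve net benefit NB(pt) = TP/n - FP/n * pt/(1-pt) at threshold
  probability pt, against treat-all and treat-none references;
* Hosmer–Lemeshow deciles-of-risk chi-square with (bins - 2) df.

Undefined denominators yield ``None`` rather than propagating NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ConfusionSummary:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _ratio(num: float, den: float):
    return num / den if den > 0 else None


def confusion_metrics(cm: ConfusionSummary) -> dict:
    """Threshold-dependent performance summary from confusion counts.

    Returns raw (unrounded) values; see :func:`render_report` for the
    conventional display rounding.
    """
    sn = _ratio(cm.TP, cm.TP + cm.FN)
    sp = _ratio(cm.TN, cm.TN + cm.FP)
    ppv = _ratio(cm.TP, cm.TP + cm.FP)
    npv = _ratio(cm.TN, cm.TN + cm.FN)
    informedness = sn + sp - 1 if None not in (sn, sp) else None
    psi = ppv + npv - 1 if None not in (ppv, npv) else None
    ppr = _ratio(ppv, 1 - npv) if None not in (ppv, npv) else None
    npr = (1 - ppv) / npv if None not in (ppv, npv) and npv > 0 else None
    return {
        "SN": sn, "SP": sp, "I": informedness,
        "PPV": ppv, "NPV": npv, "PSI": psi,
        "PPR": ppr, "NPR": npr,
        "TP": cm.TP, "FP": cm.FP, "TN": cm.TN, "FN": cm.FN,
    }


def render_report(metrics: dict) -> dict:
    """Display rounding: percentages to integers, predictive ratios to one
    decimal, I/PSI to two decimals.  Raw values stay in ``metrics``."""
    def pct(v):
        return None if v is None else int(round(100 * v))

    def dec(v, k):
        return None if v is None else round(v, k)

    return {
        "SN_pct": pct(metrics["SN"]), "SP_pct": pct(metrics["SP"]),
        "PPV_pct": pct(metrics["PPV"]), "NPV_pct": pct(metrics["NPV"]),
        "I": dec(metrics["I"], 2), "PSI": dec(metrics["PSI"], 2),
        "PPR": dec(metrics["PPR"], 1), "NPR": dec(metrics["NPR"], 1),
        # PSI recomputed from the rounded PPV/NPV chain, for comparison with
        # reports that round before summing
        "PSI_rounded_chain": (
            None if None in (metrics["PPV"], metrics["NPV"])
            else round(round(metrics["PPV"], 2) + round(metrics["NPV"], 2) - 1, 2)
        ),
    }


def confusion_from_scores(scores, labels, cutoff: float) -> ConfusionSummary:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= cutoff
    return ConfusionSummary(
        TP=int(np.sum(pred & (labels == 1))),
        FP=int(np.sum(pred & (labels == 0))),
        TN=int(np.sum(~pred & (labels == 0))),
        FN=int(np.sum(~pred & (labels == 1))),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal AUC (equals the normalised Mann–Whitney U statistic)."""
    from sklearn.metrics import roc_auc_score
    return float(roc_auc_score(labels, scores))


def _delong_ci(scores, labels, level=0.95):
    """DeLong variance of the AUC with a normal-approximation CI."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement values
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def roc_auc(scores, labels, n_boot: int = 2000, seed: int = 0,
            method: str = "bootstrap", level: float = 0.95):
    """AUC with a confidence interval.

    ``method="bootstrap"`` (default): stratified bootstrap percentile CI;
    ``method="delong"``: DeLong asymptotic CI.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    auc = _auc(scores, labels)
    if method == "delong":
        return auc, _delong_ci(scores, labels, level)[1]
    rng = np.random.default_rng(seed)
    ipos = np.flatnonzero(labels == 1)
    ineg = np.flatnonzero(labels == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(ipos, len(ipos)),
                              rng.choice(ineg, len(ineg))])
        boots[b] = _auc(scores[idx], labels[idx])
    alpha = (1 - level) / 2
    lo, hi = np.percentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return auc, (float(lo), float(hi))


def youden_cutoff(scores, labels) -> float:
    """Score threshold maximising SN + SP - 1; lowest threshold on ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    thresholds = np.unique(scores)
    n_pos = np.sum(labels == 1)
    n_neg = np.sum(labels == 0)
    best_t, best_j = thresholds[0], -np.inf
    for t in thresholds:  # ascending => lowest threshold wins ties
        pred = scores >= t
        j = (np.sum(pred & (labels == 1)) / n_pos
             + np.sum(~pred & (labels == 0)) / n_neg - 1.0)
        if j > best_j + 1e-12:
            best_t, best_j = t, j
    return float(best_t)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def hosmer_lemeshow(scores, labels, n_bins: int = 10):
    """Deciles-of-risk Hosmer–Lemeshow goodness-of-fit test.

    Bins are score quantiles; empty bins are merged (logged).  Raises if
    fewer than 3 bins remain (the chi-square has ``bins - 2`` df).
    Returns ``(statistic, p_value)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.any((scores <= 0) | (scores >= 1)):
        scores = np.clip(scores, 1e-9, 1 - 1e-9)
    edges = np.unique(np.quantile(scores, np.linspace(0, 1, n_bins + 1)))
    if len(edges) - 1 < n_bins:
        logger.info("hosmer_lemeshow: merged %d empty/duplicate bins",
                    n_bins - (len(edges) - 1))
    groups = np.clip(np.searchsorted(edges, scores, side="right") - 1,
                     0, len(edges) - 2)
    stat = 0.0
    n_groups = 0
    for g in np.unique(groups):
        sel = groups == g
        n_g = int(sel.sum())
        if n_g == 0:
            continue
        o1 = labels[sel].sum()
        e1 = scores[sel].sum()
        e0 = n_g - e1
        o0 = n_g - o1
        if e1 <= 0 or e0 <= 0:
            continue
        stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        n_groups += 1
    if n_groups < 3:
        raise ValueError("insufficient score resolution for the "
                         "Hosmer–Lemeshow test (need >= 3 bins)")
    df = n_groups - 2
    return float(stat), float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# decision-curve analysis
# ---------------------------------------------------------------------------

@dataclass
class DcaCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.treat_none is None:
            self.treat_none = np.zeros_like(self.thresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pt": self.thresholds, "model": self.net_benefit,
            "treat_all": self.treat_all, "treat_none": self.treat_none,
        })


def decision_curve(scores, labels, pt_grid=None) -> DcaCurve:
    """Net benefit of the model vs treat-all / treat-none strategies."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if pt_grid is None:
        pt_grid = np.linspace(0.01, 0.99, 99)
    pt_grid = np.asarray(pt_grid, dtype=float)
    if np.any(pt_grid >= 1.0):
        raise ValueError("pt = 1 must be excluded from the grid")
    n = len(labels)
    n_pos = labels.sum()
    n_neg = n - n_pos
    nb = np.empty_like(pt_grid)
    ta = np.empty_like(pt_grid)
    for i, pt in enumerate(pt_grid):
        w = pt / (1 - pt)
        pred = scores >= pt
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        nb[i] = tp / n - fp / n * w
        ta[i] = n_pos / n - n_neg / n * w
    return DcaCurve(pt_grid, nb, ta)


# ---------------------------------------------------------------------------
# waterfall
# ---------------------------------------------------------------------------

def waterfall_data(scores, labels, cutoff: float) -> pd.DataFrame:
    """Cut-off-shifted scores sorted ascending, with class tags.

    Zero represents the cut-off; the output is a permutation of the inputs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    shifted = scores - cutoff
    order = np.argsort(shifted, kind="stable")
    return pd.DataFrame({
        "shifted_score": shifted[order],
        "label": labels[order],
        "original_index": order,
    })


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

def evaluate_split(scores, labels, cutoff: float | None = None,
                   n_boot: int = 2000, seed: int = 0) -> dict:
    """Full metric panel for one subset at a given (or Youden) cut-off."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if cutoff is None:
        cutoff = youden_cutoff(scores, labels)
    auc, ci = roc_auc(scores, labels, n_boot=n_boot, seed=seed)
    cm = confusion_from_scores(scores, labels, cutoff)
    metrics = confusion_metrics(cm)
    out = {
        "AUC": auc, "AUC_CI95": list(ci), "cutoff": float(cutoff),
        **metrics,
        "display": render_report(metrics),
    }
    try:
        hl_stat, hl_p = hosmer_lemeshow(scores, labels)
        out["HL_stat"], out["HL_p"] = hl_stat, hl_p
    except ValueError as exc:
        out["HL_stat"], out["HL_p"] = None, None
        logger.info("Hosmer–Lemeshow skipped: %s", exc)
    return out
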