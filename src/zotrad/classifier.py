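"""Linear-SVM MVI classifier: split, CV candidate generation, final model.

Protocol:

* stratified train/test split preserving the class proportion (with the
  reference cohort of 169 = 62 MVI+ / 107 MVI- and train fraction 117/169
  this yields exactly 43/74 training and 19/33 test instances);
* repeated (default 100x) stratified 3-fold cross-validation; in each fold a
  linear-kernel SVM is trained for every value of the misclassification-cost
  grid with the per-class cost scaled by the class prior (balanced weights);
* models whose internal-validation AUC exceeds their training AUC are
  discarded (overfitting filter, implemented as printed; the direction is
  switchable via ``invert_overfit_filter``), and per CV run only the model
  with the highest validation AUC is kept — at most one candidate per run;
* every kept candidate is refit on the whole training set and the final
  model maximises (training AUC, informedness, enumeration order).

The decision value g(x) is affine in the standardised signature features; a
binomial-logit (Platt-style) mapping of g yields the *radiomic score* in
(0, 1), and the operating cut-off is the Youden threshold on the training
scores.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import LabelledDataset
from .evaluation import youden_cutoff

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)

#: the published 4-feature signature, shipped as a frozen reference model
#: for score arithmetic and unit tests — not as a claim that these
#: coefficients transfer to other data.
REFERENCE_SIGNATURE = {
    "intercept": -0.004,
    "coefficients": {
        "S-s [ZOT,A]": -0.519,
        "E-e [T,A]": -0.714,
        "U-e [ZOT,V]": 0.718,
        "S-s [ZOT,A/V]": 0.872,
    },
}


def reference_decision_value(x) -> float:
    """g(x) of the frozen reference signature at a standardized input.

    ``x`` maps feature names to values (missing names count as 0) or is a
    length-4 array ordered as the reference coefficient listing.
    """
    coefs = REFERENCE_SIGNATURE["coefficients"]
    g = REFERENCE_SIGNATURE["intercept"]
    if isinstance(x, dict):
        for name, w in coefs.items():
            g += w * x.get(name, 0.0)
    else:
        x = np.asarray(x, dtype=float)
        g += float(np.dot(list(coefs.values()), x))
    return float(g)


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def _class_train_counts(n_by_class: dict, train_fraction: float) -> dict:
    """Per-class train counts: round to nearest, then fix the total by
    largest fractional remainder so class proportions are preserved."""
    total_target = int(round(train_fraction * sum(n_by_class.values())))
    exact = {c: train_fraction * n for c, n in n_by_class.items()}
    counts = {c: int(round(v)) for c, v in exact.items()}
    diff = total_target - sum(counts.values())
    if diff != 0:
        order = sorted(exact, key=lambda c: exact[c] - np.floor(exact[c]),
                       reverse=diff > 0)
        for c in order[: abs(diff)]:
            counts[c] += 1 if diff > 0 else -1
    return counts


def split_dataset(dataset: LabelledDataset, train_fraction: float,
                  seed: int = 0):
    """Stratified train/test split; rejects empty subsets or tiny classes."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1) "
                         "(an empty test set is not allowed)")
    rng = np.random.default_rng(seed)
    n_by_class = {1: dataset.n_pos, 0: dataset.n_neg}
    if min(n_by_class.values()) < 2:
        raise ValueError("each class needs at least 2 members to split")
    counts = _class_train_counts(n_by_class, train_fraction)
    train_idx, test_idx = [], []
    for cls, k in counts.items():
        idx = np.flatnonzero(dataset.y == cls)
        if k < 1 or k >= len(idx):
            raise ValueError(f"class {cls}: split leaves an empty subset")
        rng.shuffle(idx)
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))


# ---------------------------------------------------------------------------
# CV candidate generation
# ---------------------------------------------------------------------------

@dataclass
class Candidate:
    C: float
    run: int
    val_auc: float
    train_auc: float


@dataclass
class CandidatePool:
    candidates: list
    n_discarded_overfit: int
    n_runs: int


def _fit_svm(X, y, C: float) -> SVC:
    # class_weight="balanced" scales the misclassification cost of each
    # class by the inverse class prior
    clf = SVC(kernel="linear", C=C, class_weight="balanced")
    clf.fit(X, y)
    return clf


def train_candidates(train: LabelledDataset, n_runs: int = 100,
                     n_folds: int = 3, C_grid=DEFAULT_C_GRID, seed: int = 0,
                     invert_overfit_filter: bool = False) -> CandidatePool:
    """Repeated stratified-CV candidate generation with the overfit filter.

    Per run, every (validation fold x cost) model is scored by training and
    internal-validation AUC; models with validation AUC above training AUC
    are discarded and the best surviving model (by validation AUC) is the
    run's candidate.  Runs whose models are all discarded contribute none.
    """
    X = train.X.to_numpy()
    y = train.y
    if len(np.unique(y)) != 2:
        raise ValueError("training set must contain both classes")
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % np.uint32(2**31)
    candidates: list[Candidate] = []
    n_discarded = 0
    for run in range(n_runs):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(seeds[run]))
        best: Candidate | None = None
        for tr, va in skf.split(X, y):
            for C in C_grid:
                clf = _fit_svm(X[tr], y[tr], C)
                auc_tr = roc_auc_score(y[tr], clf.decision_function(X[tr]))
                auc_va = roc_auc_score(y[va], clf.decision_function(X[va]))
                overfit = (auc_va > auc_tr) if not invert_overfit_filter \
                    else (auc_va < auc_tr)
                if overfit:
                    n_discarded += 1
                    continue
                if best is None or auc_va > best.val_auc:
                    best = Candidate(C, run, auc_va, auc_tr)
        if best is not None:
            candidates.append(best)
    if not candidates:
        raise RuntimeError(
            "every CV model was discarded by the overfit filter; "
            "more data (or a different filter direction) is needed")
    logger.info("train_candidates: %d candidates kept, %d fold-models "
                "discarded", len(candidates), n_discarded)
    return CandidatePool(candidates, n_discarded, n_runs)


# ---------------------------------------------------------------------------
# final model
# ---------------------------------------------------------------------------

@dataclass
class SignatureModel:
    """Affine decision function over named standardized features + score map."""

    feature_names: list
    coefficients: np.ndarray
    intercept: float
    platt_coef: float
    platt_intercept: float
    cutoff: float
    C: float = 1.0
    train_auc: float = float("nan")
    train_informedness: float = float("nan")
    normalization: dict | None = None
    diagnostics: dict = field(default_factory=dict)

    def decision_value(self, X) -> np.ndarray:
        X = self._as_array(X)
        return X @ self.coefficients + self.intercept

    def score(self, X) -> np.ndarray:
        g = self.decision_value(X)
        return expit(self.platt_coef * g + self.platt_intercept)

    def predict(self, X) -> np.ndarray:
        return (self.score(X) >= self.cutoff).astype(int)

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names]
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.atleast_2d(np.asarray(X, dtype=float))
        means = arr.mean(axis=0)
        if len(arr) >= 8 and np.any(np.abs(means) > 0.75):
            warnings.warn("input does not look standardized (column means "
                          "far from 0); apply the training normalization",
                          stacklevel=3)
        return arr

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "platt_coef": float(self.platt_coef),
            "platt_intercept": float(self.platt_intercept),
            "cutoff": float(self.cutoff),
            "C": float(self.C),
            "train_auc": float(self.train_auc),
            "train_informedness": float(self.train_informedness),
            "normalization": self.normalization,
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        return cls(
            d["feature_names"], np.asarray(d["coefficients"], dtype=float),
            d["intercept"], d["platt_coef"], d["platt_intercept"],
            d["cutoff"], d.get("C", 1.0), d.get("train_auc", float("nan")),
            d.get("train_informedness", float("nan")),
            d.get("normalization"), d.get("diagnostics", {}),
        )

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _informedness_at_youden(scores: np.ndarray, y: np.ndarray):
    cut = youden_cutoff(scores, y)
    pred = scores >= cut
    sn = np.mean(pred[y == 1]) if (y == 1).any() else np.nan
    sp = np.mean(~pred[y == 0]) if (y == 0).any() else np.nan
    return cut, float(sn + sp - 1.0)


def select_final(pool: CandidatePool, train: LabelledDataset) -> SignatureModel:
    """Refit every candidate on the full training set; pick the winner.

    Winner by training AUC, then informedness at the Youden cut-off, then
    candidate (enumeration) order.
    """
    if not pool.candidates:
        raise ValueError("empty candidate pool")
    X = train.X.to_numpy()
    y = train.y
    best = None
    for i, cand in enumerate(pool.candidates):
        clf = _fit_svm(X, y, cand.C)
        g = clf.decision_function(X)
        auc = roc_auc_score(y, g)
        # binomial logit mapping of the decision value -> radiomic score
        lr = LogisticRegression(C=1e6, max_iter=1000)
        lr.fit(g.reshape(-1, 1), y)
        scores = lr.predict_proba(g.reshape(-1, 1))[:, 1]
        cut, informedness = _informedness_at_youden(scores, y)
        key = (auc, informedness, -i)
        if best is None or key > best[0]:
            model = SignatureModel(
                feature_names=train.feature_names,
                coefficients=clf.coef_.ravel().copy(),
                intercept=float(clf.intercept_[0]),
                platt_coef=float(lr.coef_[0, 0]),
                platt_intercept=float(lr.intercept_[0]),
                cutoff=float(cut),
                C=cand.C,
                train_auc=float(auc),
                train_informedness=float(informedness),
                diagnostics={
                    "candidate_run": cand.run,
                    "n_candidates": len(pool.candidates),
                    "n_discarded_overfit": pool.n_discarded_overfit,
                },
            )
            best = (key, model)
    return best[1]


def radiomic_score(model: SignatureModel, X) -> np.ndarray:
    """Radiomic score (logit-mapped decision value) for standardized input."""
    return model.score(X)
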