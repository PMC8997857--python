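"""End-to-end orchestration: phantoms/cases -> features -> signature -> model.

The default protocol mirrors the development flow the package implements:
feature generation on the initial dataset (ID), normalisation + LASSO +
quadruple search on the ID, KDE/LHS oversampling of the four signature
features (producing the OD), a stratified train/test split of the OD,
repeated-CV linear-SVM training, and the full evaluation panel.

Note the default performs normalisation, selection and oversampling on the
full ID *before* the split — the faithful reproduction of the protocol this
package re-implements; every report carries a ``leakage_note`` flag for it.
Set ``oversample_before_split=False`` for a leakage-safe variant where
normalisation, selection and KDE fitting see only training rows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import classifier as clf
from . import evaluation as ev
from . import features as fb
from . import oversample as ov
from . import selection as sel
from . import zot as zd
from .data import LabelledDataset
from .io import write_feature_table
from .phantom import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults."""

    # ZOT detection
    smoothing_sigma: float = 1.0
    dilation_radius: int = 10
    half_length: int = 15
    noise_floor_frac: float = 0.10
    # feature bank
    window_radius: int = 2
    n_bins: int = 64
    # selection
    lasso_folds: int = 3
    max_retained: int = 25
    rho_max: float = 0.3
    alpha: float = 1e-3
    # oversampling
    n_new_pos: int = 30
    n_new_neg: int = 50
    lhs_runs: int = ov.DEFAULT_N_RUNS
    kde_bandwidth: str = "diffusion"
    cost: str = "product"
    # classifier
    train_fraction: float = 117.0 / 169.0
    cv_runs: int = 100
    cv_folds: int = 3
    C_grid: tuple = clf.DEFAULT_C_GRID
    invert_overfit_filter: bool = False
    # evaluation
    n_boot: int = 2000
    # protocol
    oversample_before_split: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["C_grid"] = list(d["C_grid"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "C_grid" in data:
            data["C_grid"] = tuple(data["C_grid"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


@dataclass
class RunResult:
    features: LabelledDataset
    signature: sel.QuadrupleResult
    oversampled: ov.OversampleResult | None
    model: clf.SignatureModel
    report: dict
    out_dir: pathlib.Path | None = None
    skipped_cases: list = field(default_factory=list)


def _seed_for(config: RunConfig, stage: str) -> int:
    tag = zlib.crc32(stage.encode()) % (2**31)
    base = np.random.SeedSequence([config.seed, tag])
    return int(base.generate_state(1)[0] % np.uint32(2**31))


def extract_cohort_features(cases, config: RunConfig):
    """ZOT detection + catalogue generation for every phantom case.

    Cases whose ZOT is undetectable are skipped with a warning (counted in
    the returned skip list) so a single degenerate phantom does not halt the
    cohort run.
    """
    zcfg = zd.ZotConfig(config.smoothing_sigma, config.dilation_radius,
                        config.half_length, config.noise_floor_frac)
    fcfg = fb.FeatureConfig(config.window_radius, config.n_bins,
                            config.smoothing_sigma)
    vectors, skipped = [], []
    for case in cases:
        try:
            masks, zots = {}, {}
            for phase in ("arterial", "venous"):
                img = getattr(case, phase)
                refined, zot, _ = zd.detect_zot(img, case.manual_mask, zcfg)
                masks[phase] = refined
                zots[phase] = zot.support
            vec = fb.generate_catalogue(
                {"arterial": case.arterial, "venous": case.venous},
                masks, zots, fcfg, subject_id=case.subject_id,
                label=case.label_binary)
            vectors.append(vec)
        except (zd.ZOTUndetectableError, ValueError) as exc:
            logger.warning("case %s skipped: %s", case.subject_id, exc)
            skipped.append((case.subject_id, str(exc)))
    if not vectors:
        raise RuntimeError("feature extraction failed for every case")
    import pandas as pd
    frame = pd.DataFrame([v.values for v in vectors])
    ds = LabelledDataset(frame, np.array([v.label for v in vectors]),
                         [v.subject_id for v in vectors])
    return ds, vectors, skipped


def select_signature(dataset: LabelledDataset, config: RunConfig,
                     require_significant: bool = False):
    """Normalise, LASSO-rank and quadruple-search the feature table.

    Returns ``(quadruple_result, normalization_params, ranking)``.  When the
    Holm-corrected search finds nothing significant and
    ``require_significant`` is False, the lowest-score quadruple is returned
    flagged ``significant=False`` so null cohorts still complete.
    """
    Xn, params = sel.normalize_standardize(dataset.X)
    ranking = sel.lasso_rank(Xn, dataset.y, folds=config.lasso_folds,
                             seed=_seed_for(config, "lasso"))
    retained = ranking.top(config.max_retained)
    if len(retained) < 4:
        logger.warning("LASSO retained %d features (<4); topping up by "
                       "|coefficient| rank", len(retained))
        order = ranking.coefficients.abs().sort_values(ascending=False).index
        retained = list(dict.fromkeys(list(retained) + list(order)))[:4]
    quads = sel.enumerate_quadruples(retained)
    try:
        result = sel.filter_and_test(quads, Xn, dataset.y,
                                     rho_max=config.rho_max,
                                     alpha=config.alpha)
    except sel.NoSignatureError:
        if require_significant:
            raise
        logger.warning("no significant quadruple; falling back to the "
                       "best-scoring one (flagged not significant)")
        result = sel.best_quadruple_unchecked(quads, Xn, dataset.y,
                                              rho_max=config.rho_max)
    return result, params, ranking, Xn


def run_pipeline(cohort, config: RunConfig | None = None,
                 out_dir=None) -> RunResult:
    """Execute the full flow on a phantom cohort (spec or case list).

    Every intermediate is persisted under ``out_dir`` when given; the run
    config is embedded in the report, and a fixed master seed reproduces the
    directory contents.
    """
    config = config or RunConfig()
    if isinstance(cohort, CohortSpec):
        cases = generate_cohort(cohort)
    else:
        cases = list(cohort)

    dataset, vectors, skipped = extract_cohort_features(cases, config)
    result = develop_model(dataset, config)
    result.skipped_cases = skipped
    result.report["n_cases"] = len(cases)
    result.report["n_skipped"] = len(skipped)

    if out_dir is not None:
        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_feature_table(vectors, out_dir / "features.csv")
        signature = result.signature
        with open(out_dir / "signature.json", "w") as fh:
            json.dump({"features": list(signature.features),
                       "p_value": signature.p_value,
                       "significant": signature.significant,
                       "score_rule": signature.score_rule,
                       "n_quadruples": signature.n_quadruples,
                       "n_discarded_correlated":
                           signature.n_discarded_correlated}, fh, indent=2)
        result.oversampled.dataset.to_csv(out_dir / "od.csv")
        result.model.to_json(out_dir / "model.json")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(result.report, fh, indent=2, default=_json_default)
        config.to_yaml(out_dir / "config.yaml")
        result.out_dir = out_dir
    return result


def develop_model(dataset: LabelledDataset,
                  config: RunConfig | None = None) -> RunResult:
    """Signature selection -> oversampling -> split -> SVM -> evaluation.

    Operates on an already-extracted feature table (the initial dataset).
    """
    config = config or RunConfig()
    if config.oversample_before_split:
        # faithful default: selection, normalisation and oversampling see
        # the whole initial dataset; the split happens on the OD
        signature, params, ranking, Xn = select_signature(dataset, config)
        feats = list(signature.features)
        id_sig = LabelledDataset(Xn[feats].copy(), dataset.y,
                                 list(dataset.subject_ids))
        kdes = ov.fit_class_kdes(id_sig, config.kde_bandwidth)
        ovr = ov.lhs_oversample(id_sig, kdes, config.n_new_pos,
                                config.n_new_neg, config.lhs_runs,
                                seed=_seed_for(config, "lhs"),
                                cost=config.cost)
        od = ovr.dataset
        train, test = clf.split_dataset(od, config.train_fraction,
                                        seed=_seed_for(config, "split"))
    else:
        # leakage-safe variant: the initial dataset is split first and every
        # data-driven parameter (normalisation, LASSO, quadruple search,
        # KDEs) is fit on training rows only
        id_train, id_test = clf.split_dataset(
            LabelledDataset(dataset.X.copy(), dataset.y,
                            list(dataset.subject_ids)),
            config.train_fraction, seed=_seed_for(config, "split"))
        signature, params, ranking, Xn_train = select_signature(
            id_train, config)
        feats = list(signature.features)
        train_sig = LabelledDataset(Xn_train[feats].copy(), id_train.y,
                                    list(id_train.subject_ids))
        kdes = ov.fit_class_kdes(train_sig, config.kde_bandwidth)
        ovr = ov.lhs_oversample(train_sig, kdes, config.n_new_pos,
                                config.n_new_neg, config.lhs_runs,
                                seed=_seed_for(config, "lhs"),
                                cost=config.cost)
        train = ovr.dataset
        Xn_test = params.transform(id_test.X)
        test = LabelledDataset(Xn_test[feats].copy(), id_test.y,
                               list(id_test.subject_ids))
        od = train

    pool = clf.train_candidates(train, n_runs=config.cv_runs,
                                n_folds=config.cv_folds,
                                C_grid=config.C_grid,
                                seed=_seed_for(config, "cv"),
                                invert_overfit_filter=config.invert_overfit_filter)
    model = clf.select_final(pool, train)
    model.diagnostics.update({
        "signature": feats,
        "signature_significant": signature.significant,
        "signature_p": signature.p_value,
        "score_rule": signature.score_rule,
    })

    seed_eval = _seed_for(config, "eval")
    report = {
        "config": config.to_dict(),
        "n_cases": len(dataset),
        "n_skipped": 0,
        "n_retained_lasso": len(ranking.retained),
        "signature": feats,
        "signature_significant": signature.significant,
        "signature_p_value": signature.p_value,
        "od_counts": {"total": len(od), "pos": od.n_pos, "neg": od.n_neg},
        "train_counts": {"pos": train.n_pos, "neg": train.n_neg},
        "test_counts": {"pos": test.n_pos, "neg": test.n_neg},
        "leakage_note": (
            "normalisation/selection/oversampling performed on the full "
            "initial dataset before the split (faithful default)"
            if config.oversample_before_split else
            "leakage-safe mode: normalisation/selection/KDE fit on "
            "training rows only"
        ),
        "train": ev.evaluate_split(model.score(train.X), train.y,
                                   cutoff=model.cutoff,
                                   n_boot=config.n_boot, seed=seed_eval),
        "test": ev.evaluate_split(model.score(test.X), test.y,
                                  cutoff=model.cutoff,
                                  n_boot=config.n_boot, seed=seed_eval),
    }

    return RunResult(dataset, signature, ovr, model, report)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def compare_id_od_models(id_ds: LabelledDataset, od_ds: LabelledDataset,
                         config: RunConfig | None = None) -> dict:
    """Train the CV protocol on ID and OD without an external split.

    A descriptive equivalence check: reports both training AUCs and their
    absolute difference.
    """
    config = config or RunConfig()
    if id_ds.feature_names != od_ds.feature_names:
        raise ValueError("ID and OD must share the signature features")
    out = {}
    seed = _seed_for(config, "compare")
    for tag, ds in (("ID", id_ds), ("OD", od_ds)):
        pool = clf.train_candidates(ds, n_runs=config.cv_runs,
                                    n_folds=config.cv_folds,
                                    C_grid=config.C_grid,
                                    seed=seed)
        model = clf.select_final(pool, ds)
        out[tag] = {"train_auc": model.train_auc,
                    "informedness": model.train_informedness}
    out["auc_abs_difference"] = abs(out["ID"]["train_auc"]
                                    - out["OD"]["train_auc"])
    return out
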