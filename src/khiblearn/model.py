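"""Gradient-boosted classification of Khib sites, statsmodels style.

:class:`KhibModel` is built from a :class:`~khiblearn.encoders.FeatureMatrix`
(or directly from peptide windows); ``fit()`` performs mutual-information
feature selection followed by LightGBM training and returns a
:class:`KhibResults` carrying the fitted booster, the selection, training
metadata and evaluation helpers.  Cross-validation, hyperparameter tuning and
the window-size scan hang off the model.

The booster is consumed as an engine: single-threaded deterministic mode is
the default so seeded runs are bit-reproducible on one platform.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.model_selection import StratifiedKFold

from . import metrics as _metrics
from .encoders import FeatureMatrix, encode_windows
from .selection import DEFAULT_BINS, DEFAULT_K, SelectionResult, category_report, rank_and_select
from .windows import (
    DEFAULT_SEED,
    balance_and_split,
    build_windows,
    greedy_cluster,
)


@dataclass
class BoosterParams:
    """LightGBM configuration; defaults are the tuned operating point.

    ``colsample_bytree``, ``subsample`` and ``min_child_samples`` default to
    the engine's own defaults (``None`` here) and may be searched by
    :meth:`KhibModel.tune`.
    """

    n_estimators: int = 500
    learning_rate: float = 0.1
    max_depth: int = 11
    num_leaves: int = 89
    colsample_bytree: float | None = None
    subsample: float | None = None
    min_child_samples: int | None = None
    reg_alpha: float = 1.15e-5
    reg_lambda: float = 4.4e-8

    def to_engine_kwargs(self) -> dict:
        kw = {k: v for k, v in asdict(self).items() if v is not None}
        return kw


#: search bounds for tuning: the documented tested ranges for the six printed
#: parameters, common-practice ranges for the sampling parameters
SEARCH_SPACE: dict[str, tuple] = {
    "n_estimators": ("int", 100, 1000),
    "learning_rate": ("float", 0.01, 0.1),
    "max_depth": ("int", -1, 12),
    "num_leaves": ("int", 31, 150),
    "reg_alpha": ("logfloat", 1e-8, 10.0),
    "reg_lambda": ("logfloat", 1e-8, 10.0),
    "colsample_bytree": ("float", 0.5, 1.0),
    "subsample": ("float", 0.5, 1.0),
    "min_child_samples": ("int", 5, 100),
}


def _make_booster(params: BoosterParams, seed: int, n_jobs: int = 1) -> LGBMClassifier:
    return LGBMClassifier(
        objective="binary",
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=n_jobs,
        verbosity=-1,
        **params.to_engine_kwargs(),
    )


def _check_finite(fm: FeatureMatrix) -> None:
    vals = fm.X.to_numpy()
    bad = ~np.isfinite(vals)
    if bad.any():
        cols = fm.X.columns[bad.any(axis=0)].tolist()
        raise ValueError(f"non-finite features in columns: {cols[:10]}")


def _data_hash(fm: FeatureMatrix) -> str:
    h = hashlib.blake2b(digest_size=8)
    h.update(np.ascontiguousarray(fm.X.to_numpy()).tobytes())
    h.update(np.ascontiguousarray(fm.y).tobytes())
    return h.hexdigest()


@dataclass
class CVResults:
    """Per-fold metric reports plus mean/sd aggregates."""

    fold_reports: list
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.fold_reports])

    @property
    def mean_auc(self) -> float:
        return float(self.frame()["AUC"].mean())

    @property
    def sd_auc(self) -> float:
        return float(self.frame()["AUC"].std(ddof=1))

    def summary(self) -> str:
        df = self.frame()
        lines = [f"{len(self.fold_reports)}-fold cross-validation (seed {self.seed})"]
        for col in ("ACC", "SN", "SP", "PR", "F1", "MCC", "AUC"):
            lines.append(f"  {col}: {df[col].mean():.4f} +/- {df[col].std(ddof=1):.4f}")
        return "\n".join(lines)


class KhibModel:
    """Khib site classifier: MI feature selection + gradient-boosted trees.

    Parameters
    ----------
    features : FeatureMatrix
        Hybrid feature matrix with 0/1 labels.
    params : BoosterParams, optional
        Booster configuration (tuned defaults).
    k_features : int
        Number of top-MI features to retain (default 700).
    mi_bins : int
        Equal-frequency bin count for the MI estimator.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        params: BoosterParams | None = None,
        k_features: int = DEFAULT_K,
        mi_bins: int = DEFAULT_BINS,
    ):
        _check_finite(features)
        self.features = features
        self.params = params or BoosterParams()
        self.k_features = k_features
        self.mi_bins = mi_bins

    @classmethod
    def from_windows(
        cls,
        windows,
        blocks=("esm", "ctd", "aaidx"),
        params: BoosterParams | None = None,
        k_features: int = DEFAULT_K,
        mi_bins: int = DEFAULT_BINS,
        **encode_kwargs,
    ) -> "KhibModel":
        fm = encode_windows(windows, blocks=blocks, **encode_kwargs)
        return cls(fm, params=params, k_features=k_features, mi_bins=mi_bins)

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int = DEFAULT_SEED) -> "KhibResults":
        y = self.features.y
        if min(np.sum(y == 1), np.sum(y == 0)) < 2:
            raise ValueError("need at least 2 samples per class")
        selection = rank_and_select(self.features, self.k_features, self.mi_bins)
        X = self.features.X.iloc[:, selection.selected]
        booster = _make_booster(self.params, seed)
        booster.fit(X, y)
        return KhibResults(
            model=self,
            booster=booster,
            selection=selection,
            feature_names=list(X.columns),
            seed=seed,
            data_hash=_data_hash(self.features),
        )

    # -- cross-validation ---------------------------------------------------

    def cross_validate(
        self,
        n_folds: int = 10,
        seed: int = DEFAULT_SEED,
        threshold: float = 0.5,
    ) -> CVResults:
        """Stratified k-fold CV with selection refit inside every fold."""
        y = self.features.y
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        reports = []
        for train_idx, val_idx in skf.split(np.zeros(len(y)), y):
            if np.unique(y[val_idx]).size < 2 or np.unique(y[train_idx]).size < 2:
                raise ValueError("a fold contains a single class")
            sub = self.features.subset_rows(train_idx)
            selection = rank_and_select(sub, self.k_features, self.mi_bins)
            booster = _make_booster(self.params, seed)
            booster.fit(sub.X.iloc[:, selection.selected], sub.y)
            val = self.features.subset_rows(val_idx)
            scores = booster.predict_proba(val.X.iloc[:, selection.selected])[:, 1]
            rep = _metrics.roc_auc(val.y, scores)
            cm = _metrics.confusion_metrics(val.y, scores, threshold)
            cm.auc, cm.auc_se, cm.roc = rep.auc, rep.auc_se, rep.roc
            reports.append(cm)
        return CVResults(reports, seed)

    # -- tuning -------------------------------------------------------------

    def tune(
        self,
        n_trials: int = 100,
        n_folds: int = 10,
        seed: int = DEFAULT_SEED,
        search_space: dict | None = None,
    ) -> tuple[BoosterParams, pd.DataFrame]:
        """Seeded random search over the bounded space, maximising mean CV AUC.

        Returns the best configuration and the full trial log.
        """
        if n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        space = search_space or SEARCH_SPACE
        rng = np.random.default_rng(seed)
        log = []
        best_params, best_auc = None, -np.inf
        for trial in range(n_trials):
            sampled = {}
            for name, (kind, lo, hi) in space.items():
                if kind == "int":
                    sampled[name] = int(rng.integers(lo, hi + 1))
                elif kind == "float":
                    sampled[name] = float(rng.uniform(lo, hi))
                elif kind == "logfloat":
                    sampled[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                else:
                    raise ValueError(f"unknown kind {kind!r}")
            params = BoosterParams(**sampled)
            trial_model = KhibModel(self.features, params, self.k_features, self.mi_bins)
            auc = trial_model.cross_validate(n_folds=n_folds, seed=seed).mean_auc
            log.append({"trial": trial, **sampled, "cv_auc": auc})
            if auc > best_auc:
                best_auc, best_params = auc, params
        return best_params, pd.DataFrame(log)


class KhibResults:
    """A fitted Khib classifier: booster + feature manifest + metadata."""

    def __init__(self, model, booster, selection: SelectionResult, feature_names, seed, data_hash):
        self.model = model
        self.booster = booster
        self.selection = selection
        self.feature_names = list(feature_names)
        self.seed = seed
        self.data_hash = data_hash

    # -- prediction ---------------------------------------------------------

    def _align(self, features) -> pd.DataFrame:
        X = features.X if isinstance(features, FeatureMatrix) else features
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"missing manifest columns: {missing[:10]}")
        return X[self.feature_names]

    def predict_scores(self, features) -> np.ndarray:
        """Positive-class probabilities; columns aligned by name."""
        return self.booster.predict_proba(self._align(features))[:, 1]

    def predict(self, features, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_scores(features) >= threshold).astype(int)

    def evaluate(self, features, threshold: float = 0.5) -> _metrics.MetricsReport:
        fm = features
        scores = self.predict_scores(fm)
        rep = _metrics.roc_auc(fm.y, scores)
        cm = _metrics.confusion_metrics(fm.y, scores, threshold)
        cm.auc, cm.auc_se, cm.roc = rep.auc, rep.auc_se, rep.roc
        return cm

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        pct = category_report(self.selection)
        lines = [
            "KhibModel fit summary",
            "=" * 52,
            f"samples:            {self.model.features.n_samples}",
            f"features (input):   {self.model.features.n_features}",
            f"features (kept):    {len(self.feature_names)}",
            "category mix (%):   "
            + ", ".join(f"{c}={p}" for c, p in pct.items()),
            f"seed:               {self.seed}",
            f"data hash:          {self.data_hash}",
            "booster params:",
        ]
        for k, v in asdict(self.model.params).items():
            if v is not None:
                lines.append(f"  {k} = {v}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------

    def save(self, directory) -> None:
        """Persist as engine-native model text plus a JSON manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.booster.booster_.save_model(str(d / "booster.txt"))
        manifest = {
            "feature_names": self.feature_names,
            "seed": self.seed,
            "data_hash": self.data_hash,
            "params": asdict(self.model.params),
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @staticmethod
    def load_scorer(directory):
        """Load a saved model as a (scores_fn, manifest) pair.

        The returned callable maps an aligned DataFrame / FeatureMatrix to
        positive-class probabilities.
        """
        import lightgbm as lgb

        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        booster = lgb.Booster(model_file=str(d / "booster.txt"))
        names = manifest["feature_names"]

        def score(features):
            X = features.X if isinstance(features, FeatureMatrix) else features
            missing = [c for c in names if c not in X.columns]
            if missing:
                raise KeyError(f"missing manifest columns: {missing[:10]}")
            return booster.predict(X[names])

        return score, manifest


# ---------------------------------------------------------------------------
# pipeline-level operations
# ---------------------------------------------------------------------------

def run_pipeline_cv(
    windows,
    k_features: int = DEFAULT_K,
    n_folds: int = 10,
    seed: int = DEFAULT_SEED,
    blocks=("esm", "ctd", "aaidx"),
    params: BoosterParams | None = None,
    **encode_kwargs,
) -> CVResults:
    """Encode labelled windows, select features, cross-validate the booster."""
    model = KhibModel.from_windows(
        windows, blocks=blocks, params=params, k_features=k_features, **encode_kwargs
    )
    return model.cross_validate(n_folds=n_folds, seed=seed)


def window_size_scan(
    proteins,
    sites,
    sizes=tuple(range(35, 48, 2)),
    identity_threshold: float = 0.4,
    n_folds: int = 10,
    seed: int = DEFAULT_SEED,
    k_features: int = DEFAULT_K,
    blocks=("esm", "ctd", "aaidx"),
    params: BoosterParams | None = None,
) -> pd.DataFrame:
    """Mean CV AUC of the full pipeline for each odd window size.

    For every size the pipeline re-extracts windows (flank = (size-1)/2),
    clusters both classes, balances by representatives, encodes, selects and
    cross-validates with a fixed seed.
    """
    rows = []
    for size in sizes:
        if size % 2 == 0:
            raise ValueError(f"window sizes must be odd, got {size}")
        flank = (size - 1) // 2
        pos, neg = build_windows(proteins, sites, flank=flank)
        pos_cl = greedy_cluster(pos, identity_threshold)
        neg_cl = greedy_cluster(neg, identity_threshold)
        selected, _ = balance_and_split(pos, pos_cl, neg, neg_cl, n_folds=n_folds, seed=seed)
        cv = run_pipeline_cv(
            selected, k_features=k_features, n_folds=n_folds, seed=seed,
            blocks=blocks, params=params,
        )
        rows.append({"window_size": size, "flank": flank,
                     "mean_cv_auc": cv.mean_auc, "sd_cv_auc": cv.sd_auc})
    return pd.DataFrame(rows)
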