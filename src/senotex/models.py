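"""Quality control, embedding and phenotype classification on feature tables.

The QC stage trains a random forest on the full feature vectors (auxiliary
bookkeeping features included) of manually labeled good/bad images, then
chooses the smallest good-class probability threshold whose out-of-fold,
cross-validated precision reaches the target (default 95%).  The calibrated
threshold is applied to unlabeled images; only images classified as good
proceed.

Phenotype classification standardizes non-auxiliary features on the
training conditions (proliferating and senescent) only, fits an RBF support
vector machine, and reports the fraction of each treated group classified
as either phenotype; a group is called ambiguous when neither fraction
reaches 0.7.  A t-SNE embedding of the same feature block supports visual
inspection and never feeds classification.

All missing feature values (degenerate GLCM slices, empty masks) are
median-imputed with medians learned from training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .texture import AUX_FEATURES

__all__ = [
    "Standardizer",
    "MedianImputer",
    "QCParams",
    "QCModel",
    "ConditionModel",
    "ConfusionSummary",
    "EmbeddingResult",
    "standardize",
    "train_qc",
    "apply_qc",
    "embed",
    "train_condition",
    "classify_treated",
    "condition_summaries",
    "feature_columns",
]

REJECT_ALL = 1.0 + 1e-9  # threshold sentinel: no operating point reaches target
AMBIGUITY_FRACTION = 0.7


def feature_columns(df: pd.DataFrame, include_aux: bool = True) -> list[str]:
    """Feature columns of a table (``meta_*`` provenance columns excluded)."""
    cols = [c for c in df.columns if not c.startswith("meta_")]
    if not include_aux:
        cols = [c for c in cols if c not in AUX_FEATURES]
    return cols


@dataclass
class MedianImputer:
    medians: pd.Series

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "MedianImputer":
        med = X.median(numeric_only=True)
        return cls(medians=med.fillna(0.0))

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.fillna(self.medians)


@dataclass
class Standardizer:
    """Column-wise z-scoring with stored training statistics."""

    mean: pd.Series
    sd: pd.Series
    zero_variance: list[str]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        sd = self.sd.replace(0.0, 1.0)
        Z = (X - self.mean) / sd
        for c in self.zero_variance:
            if c in Z.columns:
                Z[c] = 0.0
        return Z


def standardize(
    X: pd.DataFrame, fit_stats: Standardizer | None = None
) -> tuple[pd.DataFrame, Standardizer]:
    """Z-score columns; zero-variance columns map to 0 and are flagged.

    When ``fit_stats`` is given the stored statistics are applied without
    refitting (held-out data therefore need not come out centred).
    """
    if fit_stats is None:
        if len(X) < 2:
            raise ValueError("need >= 2 rows to fit standardization statistics")
        mean = X.mean()
        sd = X.std(ddof=0)
        zero_var = [c for c in X.columns if sd[c] == 0.0 or not np.isfinite(sd[c])]
        fit_stats = Standardizer(mean=mean, sd=sd, zero_variance=zero_var)
    return fit_stats.transform(X), fit_stats


@dataclass(frozen=True)
class QCParams:
    n_trees: int = 500
    n_folds: int = 5
    target_precision: float = 0.95
    seed: int = 0


@dataclass
class QCModel:
    classifier: RandomForestClassifier
    imputer: MedianImputer
    standardizer: Standardizer
    threshold: float
    target_precision: float
    feature_names: list[str]
    calibration: pd.DataFrame  # out-of-fold (probability, label) pairs
    seed: int

    @property
    def reject_all(self) -> bool:
        return self.threshold > 1.0


def _oof_probabilities(
    X: pd.DataFrame, y: np.ndarray, params: QCParams
) -> np.ndarray:
    """Out-of-fold good-class probabilities via stratified k-fold CV."""
    oof = np.full(len(y), np.nan)
    skf = StratifiedKFold(
        n_splits=params.n_folds, shuffle=True, random_state=params.seed
    )
    for tr, va in skf.split(X, y):
        imp = MedianImputer.fit(X.iloc[tr])
        Xt, stats = standardize(imp.transform(X.iloc[tr]))
        rf = RandomForestClassifier(
            n_estimators=params.n_trees, random_state=params.seed, n_jobs=1
        ).fit(Xt, y[tr])
        Xv, _ = standardize(imp.transform(X.iloc[va]), stats)
        good_col = list(rf.classes_).index(1)
        oof[va] = rf.predict_proba(Xv)[:, good_col]
    return oof


def _calibrate_threshold(
    oof: np.ndarray, y: np.ndarray, target: float, min_keep: int = 1
) -> float:
    """Smallest threshold whose out-of-fold precision reaches the target.

    Operating points keeping fewer than ``min_keep`` records are ignored so
    that an uninformative scorer cannot calibrate on a handful of lucky
    top-ranked points.
    """
    for t in np.unique(oof):
        kept = oof >= t
        if kept.sum() >= min_keep:
            precision = y[kept].mean()
            if precision >= target:
                return float(t)
    return REJECT_ALL


def train_qc(
    features: pd.DataFrame,
    labels,
    params: QCParams | None = None,
) -> QCModel:
    """Train the QC random forest and calibrate its decision threshold.

    ``labels`` are truthy for good images.  The threshold is chosen purely
    from cross-validated out-of-fold predictions (never from any test
    data); if no operating point reaches the target precision a reject-all
    sentinel threshold is stored and a warning is raised.
    """
    params = params or QCParams()
    y = np.asarray([1 if bool(l) else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("both good and bad examples are required")
    if len(y) < 2 * params.n_folds:
        raise ValueError("need at least 2 x n_folds labeled images")
    cols = feature_columns(features, include_aux=True)
    X = features[cols]

    oof = _oof_probabilities(X, y, params)
    min_keep = max(1, int(0.05 * len(y)))
    threshold = _calibrate_threshold(oof, y, params.target_precision, min_keep)
    if threshold > 1.0:
        warnings.warn(
            "no probability threshold reaches the target precision; "
            "QC model will reject all images",
            stacklevel=2,
        )

    imputer = MedianImputer.fit(X)
    Xt, stats = standardize(imputer.transform(X))
    rf = RandomForestClassifier(
        n_estimators=params.n_trees, random_state=params.seed, n_jobs=1
    ).fit(Xt, y)
    calib = pd.DataFrame({"oof_probability": oof, "label_good": y})
    return QCModel(
        classifier=rf, imputer=imputer, standardizer=stats,
        threshold=threshold, target_precision=params.target_precision,
        feature_names=cols, calibration=calib, seed=params.seed,
    )


def qc_probabilities(model: QCModel, features: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing columns: {missing[:5]}")
    X = features[model.feature_names]
    Xt, _ = standardize(model.imputer.transform(X), model.standardizer)
    good_col = list(model.classifier.classes_).index(1)
    return model.classifier.predict_proba(Xt)[:, good_col]


def apply_qc(model: QCModel, features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Keep decision and good-class probability per record."""
    proba = qc_probabilities(model, features)
    return proba >= model.threshold, proba


@dataclass
class EmbeddingResult:
    coords: np.ndarray
    perplexity: float
    seed: int


def embed(
    features: pd.DataFrame, perplexity: float = 30.0, seed: int = 0
) -> EmbeddingResult:
    """Deterministic 2D t-SNE of non-auxiliary features."""
    cols = feature_columns(features, include_aux=False)
    X = features[cols]
    if len(X) <= 3 * perplexity:
        raise ValueError(
            f"t-SNE needs n > 3 x perplexity (n={len(X)}, perplexity={perplexity})"
        )
    imp = MedianImputer.fit(X)
    Z, _ = standardize(imp.transform(X))
    ts = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed,
        init="pca", learning_rate="auto", n_jobs=1,
    )
    coords = ts.fit_transform(Z.to_numpy())
    return EmbeddingResult(coords=np.asarray(coords), perplexity=perplexity, seed=seed)


@dataclass
class ConditionModel:
    classifier: SVC
    imputer: MedianImputer
    standardizer: Standardizer
    feature_names: list[str]
    classes: tuple[str, str] = ("proliferating", "senescent")
    train_accuracy: float = float("nan")


def train_condition(
    features: pd.DataFrame,
    labels,
    kernel: str = "rbf",
    C: float = 1.0,
    classes: tuple[str, str] = ("proliferating", "senescent"),
) -> ConditionModel:
    """Fit the proliferating-vs-senescent SVM on training conditions only."""
    y = np.asarray(labels)
    present = set(np.unique(y))
    if not set(classes) <= present:
        raise ValueError(f"both classes {classes} must be present; got {present}")
    if not present <= set(classes):
        raise ValueError(f"unexpected labels {present - set(classes)} in training data")
    cols = feature_columns(features, include_aux=False)
    X = features[cols]
    imp = MedianImputer.fit(X)
    Z, stats = standardize(imp.transform(X))
    svm = SVC(kernel=kernel, C=C).fit(Z, y)
    acc = float((svm.predict(Z) == y).mean())
    return ConditionModel(
        classifier=svm, imputer=imp, standardizer=stats,
        feature_names=cols, classes=classes, train_accuracy=acc,
    )


def predict_condition(model: ConditionModel, features: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing columns: {missing[:5]}")
    X = features[model.feature_names]
    Z, _ = standardize(model.imputer.transform(X), model.standardizer)
    return model.classifier.predict(Z)


@dataclass
class ConfusionSummary:
    """Per treated group: fraction classified as each training phenotype."""

    fractions: dict[str, dict[str, float]] = field(default_factory=dict)

    def call(self, group: str) -> str:
        fr = self.fractions[group]
        best = max(("proliferating", "senescent"), key=lambda c: fr[c])
        return best if fr[best] >= AMBIGUITY_FRACTION else "ambiguous"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "fraction_classified_proliferating": fr["proliferating"],
                "fraction_classified_senescent": fr["senescent"],
                "n": int(fr["n"]),
                "call": self.call(g),
            }
            for g, fr in self.fractions.items()
        ]
        return pd.DataFrame(rows)


def classify_treated(
    model: ConditionModel, treated: dict[str, pd.DataFrame]
) -> ConfusionSummary:
    """Classify treated groups; fractions sum to 1 per non-empty group."""
    out = ConfusionSummary()
    for group, df in treated.items():
        if len(df) == 0:
            warnings.warn(f"treated group {group!r} is empty; omitted", stacklevel=2)
            continue
        pred = predict_condition(model, df)
        f_sen = float((pred == "senescent").mean())
        out.fractions[group] = {
            "proliferating": 1.0 - f_sen,
            "senescent": f_sen,
            "n": len(df),
        }
    return out


DEFAULT_SUMMARY_FEATURES = ("area_px", "glcm_energy_d4_a0", "glcm_dissimilarity_d2_a90")


def condition_summaries(
    features: pd.DataFrame,
    labels,
    summary_features=DEFAULT_SUMMARY_FEATURES,
) -> pd.DataFrame:
    """Box-plot-ready per-condition distribution table.

    Defaults to the three headline readouts: nuclear area, GLCM energy at
    distance 4 along the x-axis, and GLCM dissimilarity at distance 2 along
    the y-axis.
    """
    y = np.asarray(labels)
    rows = []
    if len(features) != len(y):
        raise ValueError("labels must align with feature rows")
    for cond in pd.unique(y):
        sub = features.loc[y == cond]
        for feat in summary_features:
            vals = sub[feat].dropna()
            rows.append(
                {
                    "condition": cond,
                    "feature": feat,
                    "n": int(len(vals)),
                    "q25": float(vals.quantile(0.25)) if len(vals) else float("nan"),
                    "median": float(vals.median()) if len(vals) else float("nan"),
                    "q75": float(vals.quantile(0.75)) if len(vals) else float("nan"),
                }
            )
    return pd.DataFrame(
        rows, columns=["condition", "feature", "n", "q25", "median", "q75"]
    )
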