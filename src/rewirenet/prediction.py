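"""Cross-year prediction of pregnancy outcome from PWBC transcript levels.

Protocol: genes differential between AI-pregnant and non-pregnant heifers in
a year-adjusted NB model (cohort year as a fixed effect, Benjamini-Hochberg
FDR < 0.03) form the feature panel; counts for the panel are
variance-stabilized (log2 of normalized counts + 0.5, then per-gene
centering/scaling with training-cohort parameters only); classifiers train
on the year-one cohort and blind-predict the year-two cohort. A registry of
classifier families is screened by cross-validated training accuracy, and
the chosen algorithm (random forest by default, 500 trees, sqrt-p features
per split) is refit under many seeds; the distribution of correctly
classified test samples over seeds and the mean impurity importance per
gene are the outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .diffexpr import nb_dispersion, nb_wald_test, normalization_factors, normalized_counts
from .io import CountMatrix, Outcome, SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "FeaturePanel",
    "PredictionRun",
    "select_panel",
    "vst_transform",
    "default_registry",
    "screen_algorithms",
    "seed_sweep",
    "accuracy",
    "accuracy_pvalue",
]


@dataclass
class FeaturePanel:
    """Ordered gene panel with per-gene transform parameters estimated on
    the training cohort only."""

    genes: list[str]
    mean: pd.Series | None = None
    scale: pd.Series | None = None


@dataclass
class PredictionRun:
    seed: int
    predicted: pd.Series  # label per test sample
    n_correct: int
    accuracy: float


def select_panel(
    cm_combined: CountMatrix,
    samples: SampleTable,
    focal: str = Outcome.AI_PREG.value,
    reference: str = Outcome.NON_PREG.value,
    fdr_threshold: float = 0.03,
) -> FeaturePanel:
    """Year-adjusted DE panel: genes with BH FDR < threshold for the group
    coefficient of the NB Wald model with year as a fixed effect, fit on
    both cohorts combined."""
    groups = samples.outcomes(cm_combined.sample_ids)
    use = groups.isin([focal, reference]).to_numpy()
    sub = cm_combined.subset_samples(np.array(cm_combined.sample_ids)[use])
    years = samples.years(sub.sample_ids)
    for y in years.unique():
        present = set(samples.outcomes(sub.sample_ids)[years == y])
        if not {focal, reference} <= present:
            raise ValueError(f"year {y} lacks one of the contrast groups")
    factors = normalization_factors(sub)
    disp = nb_dispersion(sub, samples.outcomes(sub.sample_ids), factors)
    res = nb_wald_test(sub, samples, focal, reference, disp, factors, year_covariate=True)
    fdr = multipletests(res["p_wald"].to_numpy(), method="fdr_bh")[1]
    genes = list(res.index[fdr < fdr_threshold])
    if not genes:
        raise ValueError(
            "no genes pass the panel FDR threshold; relax fdr_threshold"
        )
    logger.info("panel: %d genes at FDR < %s", len(genes), fdr_threshold)
    return FeaturePanel(genes)


def vst_transform(
    cm: CountMatrix,
    panel: FeaturePanel,
    fit: bool = False,
) -> pd.DataFrame:
    """Variance-stabilizing transform of panel genes: log2(normalized count
    + 0.5), then per-gene centering and scaling.

    With ``fit=True`` the transform parameters are estimated from this
    (training) matrix and stored on the panel; otherwise the stored
    training parameters are reused unchanged. Zero-variance genes get
    scale 1 (flagged). Returns samples x genes."""
    missing = set(panel.genes) - set(cm.feature_ids)
    if missing:
        raise KeyError(f"panel genes absent from matrix: {sorted(missing)[:5]}")
    factors = normalization_factors(cm)
    norm = normalized_counts(cm, factors).loc[panel.genes]
    logv = np.log2(norm + 0.5)
    if fit:
        mu = logv.mean(axis=1)
        sd = logv.std(axis=1, ddof=1)
        flat = sd == 0
        if flat.any():
            logger.info("%d panel genes with zero training variance; scale 1", int(flat.sum()))
            sd = sd.mask(flat, 1.0)
        panel.mean, panel.scale = mu, sd
    if panel.mean is None or panel.scale is None:
        raise ValueError("transform parameters not fitted; call with fit=True on training data")
    z = (logv.sub(panel.mean, axis=0)).div(panel.scale, axis=0)
    return z.T  # samples x genes


def default_registry() -> dict[str, callable]:
    """Classifier families screened in place of the original wide sweep."""
    return {
        "random_forest": lambda seed: RandomForestClassifier(
            n_estimators=500, max_features="sqrt", random_state=seed
        ),
        "lda": lambda seed: LinearDiscriminantAnalysis(),
        "logistic_l2": lambda seed: make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        ),
        "svm_rbf": lambda seed: make_pipeline(StandardScaler(), SVC(random_state=seed)),
        "knn": lambda seed: KNeighborsClassifier(n_neighbors=3),
    }


def screen_algorithms(
    train: pd.DataFrame,
    labels: pd.Series,
    registry: dict | None = None,
    k_folds: int = 3,
    seed: int = 0,
    flag_threshold: float = 0.9,
) -> pd.DataFrame:
    """Stratified cross-validated training accuracy per registry algorithm;
    algorithms at or above ``flag_threshold`` are flagged for the sweep."""
    registry = registry or default_registry()
    y = labels.loc[train.index].to_numpy()
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    rows = []
    for name, factory in sorted(registry.items()):
        acc = cross_val_score(factory(seed), train.to_numpy(), y, cv=cv, scoring="accuracy")
        rows.append({"algorithm": name, "cv_accuracy": float(acc.mean())})
    out = pd.DataFrame(rows)
    out["flagged"] = out["cv_accuracy"] >= flag_threshold
    return out.sort_values("cv_accuracy", ascending=False).reset_index(drop=True)


def accuracy(pred, truth) -> float:
    """Fraction of test samples classified correctly."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return float((pred == truth).mean())


def accuracy_pvalue(n_correct: int, n_test: int, majority_fraction: float) -> float:
    """Exact one-sided binomial p of the observed accuracy against the
    no-information (majority-class) rate."""
    return float(stats.binom.sf(n_correct - 1, n_test, majority_fraction))


def seed_sweep(
    train: pd.DataFrame,
    test: pd.DataFrame,
    labels_train: pd.Series,
    labels_test: pd.Series,
    algorithm=None,
    n_runs: int = 2000,
    base_seed: int = 0,
) -> tuple[list[PredictionRun], pd.DataFrame, pd.Series]:
    """Repeated fit/predict runs differing only in seed (seed_i = base_seed
    + i). Returns the runs, a histogram of n_correct over runs, and the mean
    impurity-based importance per gene (ranked, non-negative)."""
    if n_runs < 1:
        raise ValueError("need at least one run")
    if algorithm is None:
        algorithm = default_registry()["random_forest"]
    y_tr = labels_train.loc[train.index].to_numpy()
    y_te = labels_test.loc[test.index].to_numpy()
    runs: list[PredictionRun] = []
    imp = np.zeros(train.shape[1])
    n_imp = 0
    for i in range(n_runs):
        seed = base_seed + i
        clf = algorithm(seed)
        clf.fit(train.to_numpy(), y_tr)
        pred = clf.predict(test.to_numpy())
        n_correct = int((pred == y_te).sum())
        runs.append(
            PredictionRun(seed, pd.Series(pred, index=test.index), n_correct, n_correct / len(y_te))
        )
        if hasattr(clf, "feature_importances_"):
            imp += clf.feature_importances_
            n_imp += 1
    counts = np.bincount([r.n_correct for r in runs], minlength=len(y_te) + 1)
    hist = pd.DataFrame({"n_correct": np.arange(len(counts)), "n_runs": counts})
    importance = pd.Series(
        imp / n_imp if n_imp else np.zeros(train.shape[1]),
        index=train.columns,
        name="importance",
    ).sort_values(ascending=False)
    return runs, hist, importance
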