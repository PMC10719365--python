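"""Cohort-level statistics and machine learning on chrometric profiles.

The analysis layer turns per-cell feature tables into condition-level
conclusions while guarding against the two failure modes of patient
cohorts: patient-identity leakage and patient-dominance. Leakage is
prevented by leave-one-patient-out cross-validation (LOPO-CV) — a random
forest never sees cells of the patient it is evaluated on — and dominance
by balanced subsampling to equal per-patient cell counts before any model
is fit. Chance level is estimated empirically by re-running the identical
LOPO protocol on label-permuted tables. Biomarkers are screened two ways,
by Gini importance of the fitted forests and by per-feature Welch tests
with Benjamini-Hochberg control, and the two rankings can be compared.

A feature table is a pandas DataFrame with one row per cell, the metadata
columns ``patient_id, condition, timepoint, sample_id`` (plus anything
else non-numeric) and numeric feature columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.metrics import balanced_accuracy_score, confusion_matrix
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RFConfig",
    "CVResult",
    "ScreenResult",
    "AblationResult",
    "metadata_columns",
    "feature_columns",
    "balance_sample",
    "prune_correlated",
    "balanced_accuracy",
    "lopo_cv_rfc",
    "patient_majority_vote",
    "permutation_baseline",
    "ablation_patients",
    "ablation_cells",
    "gini_ranking",
    "welch_screen_bh",
    "compare_to_control",
    "significance_stars",
    "qc_embedding",
]

METADATA_COLUMNS = ("nucleus_id", "sample_id", "patient_id", "condition", "timepoint", "cell_type", "subset")


def metadata_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c in METADATA_COLUMNS or not pd.api.types.is_numeric_dtype(table[c])]


def feature_columns(table: pd.DataFrame) -> list[str]:
    meta = set(metadata_columns(table))
    return [c for c in table.columns if c not in meta]


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings used in every classification protocol.

    500 trees with sqrt(n_features) candidate features per split and no
    depth cap; analyses at reduced scale may lower ``n_estimators``.
    """

    n_estimators: int = 500
    max_features: str | float = "sqrt"
    max_depth: int | None = None
    n_jobs: int = 1

    def build(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            random_state=int(seed) % (2**31),
            n_jobs=self.n_jobs,
        )


@dataclass
class CVResult:
    """Leave-one-patient-out cross-validation outputs."""

    classes: list[str]
    fold_patients: list[str]
    fold_scores: np.ndarray  # per-fold balanced accuracy
    confusion: np.ndarray  # average of row-normalized per-fold confusion matrices
    predictions: pd.DataFrame  # per-cell: patient_id, y_true, y_pred
    importances: np.ndarray  # folds x features, Gini importance
    feature_names: list[str]
    sensitivity: float | None = None  # binary tasks: recall of classes[1]
    specificity: float | None = None  # binary tasks: recall of classes[0]

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def sd_score(self) -> float:
        return float(np.std(self.fold_scores, ddof=1)) if len(self.fold_scores) > 1 else 0.0


@dataclass
class ScreenResult:
    """Per-feature Welch screen with BH-adjusted p-values."""

    table: pd.DataFrame  # feature, group_a, group_b, statistic, p_raw, p_adj, mean_a, mean_b, direction, significant, stars
    alpha: float = 0.05

    @property
    def significant_features(self) -> list[str]:
        sig = self.table[self.table["significant"]]
        return list(dict.fromkeys(sig["feature"]))


@dataclass
class AblationResult:
    grid: list  # k values (patients) or p values (cell fractions)
    scores: np.ndarray  # len(grid) x reps, mean LOPO balanced accuracy
    summary: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.summary is None:
            self.summary = pd.DataFrame(
                {
                    "grid": self.grid,
                    "mean": self.scores.mean(axis=1),
                    "sd": self.scores.std(axis=1, ddof=1) if self.scores.shape[1] > 1 else 0.0,
                }
            )


# ---------------------------------------------------------------------------
# sampling and pruning
# ---------------------------------------------------------------------------

def balance_sample(
    table: pd.DataFrame,
    n: int,
    by: str = "patient_id",
    within: Sequence[str] = (),
    seed: int = 0,
    patient_col: str = "patient_id",
) -> pd.DataFrame:
    """Draw a patient-balanced random subset.

    ``n`` rows are taken from every level of ``by`` (e.g. 185 per patient,
    or 772 per tumor group), allocated as equally as possible across the
    sub-units formed by ``patient_col`` and any additional ``within``
    columns so that no patient (or patient-timepoint) dominates. Levels of
    ``by`` whose sub-units cannot jointly supply ``n`` cells are excluded —
    the "with sufficient cells" rule. Reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    table = table.reset_index(drop=True)
    unit_cols = [patient_col] + [c for c in within if c != patient_col]
    if by in unit_cols:
        unit_cols = [c for c in unit_cols if c != by] or [by]
    pieces = []
    for level in sorted(table[by].astype(str).unique()):
        sub = table[table[by].astype(str) == level]
        units = sorted(sub.groupby(unit_cols, sort=True).groups.items())
        k = len(units)
        base, extra = divmod(n, k)
        quota = {key: base + (1 if i < extra else 0) for i, (key, _) in enumerate(units)}
        if any(len(idx) < quota[key] for key, idx in units):
            continue  # insufficient cells in some sub-unit: exclude this level
        for key, idx in units:
            take = rng.choice(np.asarray(idx), size=quota[key], replace=False)
            pieces.append(table.loc[np.sort(take)])
    if not pieces:
        raise ValueError(f"no level of '{by}' meets the {n}-cell floor")
    return pd.concat(pieces, axis=0).reset_index(drop=True)


def prune_correlated(
    table: pd.DataFrame, r_thresh: float = 0.8, features: Sequence[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Remove features correlated with any other at |Pearson r| > ``r_thresh``.

    Greedy in fixed column order: when a pair offends, the later column is
    dropped and the earlier one kept, so the surviving set is deterministic.
    Constant columns have undefined correlation and are removed first with
    a warning. A pair at exactly ``r_thresh`` is kept (strict inequality).
    Returns the pruned table and the removed feature names.
    """
    feats = list(features) if features is not None else feature_columns(table)
    if len(feats) < 2 or len(table) < 3:
        raise ValueError("need >= 2 features and >= 3 rows")
    removed = []
    X = table[feats]
    constant = [c for c in feats if X[c].nunique(dropna=False) <= 1]
    if constant:
        warnings.warn(f"removing constant feature columns (undefined correlation): {constant}")
        removed.extend(constant)
        feats = [c for c in feats if c not in constant]
    corr = table[feats].corr(method="pearson").abs().to_numpy()
    keep: list[int] = []
    for j in range(len(feats)):
        if any(corr[j, i] > r_thresh for i in keep):
            removed.append(feats[j])
        else:
            keep.append(j)
    kept = [feats[j] for j in keep]
    meta = metadata_columns(table)
    return table[meta + kept], removed


# ---------------------------------------------------------------------------
# classification protocols
# ---------------------------------------------------------------------------

def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of per-class recall over the classes present in ``y_true``."""
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("empty input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # classes present only in y_pred
        return float(balanced_accuracy_score(y_true, np.asarray(y_pred)))


def lopo_cv_rfc(
    table: pd.DataFrame,
    label_col: str = "condition",
    features: Sequence[str] | None = None,
    rf: RFConfig = RFConfig(),
    seed: int = 0,
    patient_col: str = "patient_id",
    allow_mixed_patients: bool = False,
) -> CVResult:
    """Leave-one-patient-out cross-validated random-forest classification.

    One fold per patient: the forest trains on every other patient's cells
    and is scored by balanced accuracy on the held-out patient's cells, so
    patient-specific chromatin signatures cannot leak into the evaluation.
    Returns per-fold scores, the average row-normalized confusion matrix
    (rows without test support in a fold are excluded from that fold's
    average), per-cell predictions and per-fold Gini importances. For
    binary tasks, sensitivity/specificity are the mean recalls of the
    second/first class over the folds where that class is held out.

    A patient carrying more than one label is a leakage hazard and raises,
    unless ``allow_mixed_patients`` (used by the permutation baseline,
    where permuted labels necessarily mix within patients).
    """
    feats = list(features) if features is not None else feature_columns(table)
    feats = [f for f in feats if f != label_col]
    labels = table[label_col].astype(str)
    classes = sorted(labels.unique())
    if not allow_mixed_patients:
        per_patient = table.groupby(patient_col)[label_col].nunique()
        bad = per_patient[per_patient > 1]
        if len(bad):
            raise ValueError(f"label leakage: patients with >1 class: {list(bad.index)}")
    patients = sorted(table[patient_col].astype(str).unique())
    if len(patients) < 2:
        raise ValueError("need >= 2 patients for LOPO-CV")

    rng = np.random.default_rng(seed)
    X = table[feats].to_numpy(float)
    y = labels.to_numpy()
    pid = table[patient_col].astype(str).to_numpy()

    fold_scores, confusions, importances, preds = [], [], [], []
    class_recalls: dict[str, list[float]] = {c: [] for c in classes}
    for p in patients:
        test = pid == p
        clf = rf.build(rng.integers(2**31))
        clf.fit(X[~test], y[~test])
        y_hat = clf.predict(X[test])
        fold_scores.append(balanced_accuracy(y[test], y_hat))
        cm = confusion_matrix(y[test], y_hat, labels=classes).astype(float)
        support = cm.sum(axis=1)
        norm = np.full_like(cm, np.nan)
        present = support > 0
        norm[present] = cm[present] / support[present, None]
        confusions.append(norm)
        for ci, c in enumerate(classes):
            if present[ci]:
                class_recalls[c].append(norm[ci, ci])
        importances.append(clf.feature_importances_)
        preds.append(pd.DataFrame({patient_col: p, "y_true": y[test], "y_pred": y_hat}))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        confusion = np.nanmean(np.stack(confusions), axis=0)
    sens = spec = None
    if len(classes) == 2:
        spec = float(np.mean(class_recalls[classes[0]])) if class_recalls[classes[0]] else None
        sens = float(np.mean(class_recalls[classes[1]])) if class_recalls[classes[1]] else None
    return CVResult(
        classes=classes,
        fold_patients=patients,
        fold_scores=np.asarray(fold_scores),
        confusion=confusion,
        predictions=pd.concat(preds, ignore_index=True),
        importances=np.stack(importances),
        feature_names=feats,
        sensitivity=sens,
        specificity=spec,
    )


def patient_majority_vote(cv: CVResult, patient_col: str = "patient_id") -> pd.DataFrame:
    """Patient-level diagnosis by majority vote over per-cell predictions.

    Each patient gets the modal predicted class; exact ties break
    deterministically to the first class in sorted order and are flagged
    ``ambiguous``. The returned frame has one row per patient plus a
    ``correct`` column; overall patient accuracy is ``df['correct'].mean()``.
    """
    rows = []
    for p, sub in cv.predictions.groupby(patient_col, sort=True):
        counts = sub["y_pred"].value_counts()
        top = counts.max()
        winners = sorted(counts[counts == top].index)
        truth = sub["y_true"].iloc[0]
        rows.append(
            {
                patient_col: p,
                "call": winners[0],
                "truth": truth,
                "correct": winners[0] == truth,
                "ambiguous": len(winners) > 1,
                "vote_fraction": top / len(sub),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PermutationBaseline:
    null_fold_scores: np.ndarray  # n_perm x n_folds
    null_means: np.ndarray  # per-permutation mean balanced accuracy
    real_fold_scores: np.ndarray
    wilcoxon_statistic: float
    p_value: float  # two-sided Wilcoxon rank-sum, real vs pooled null folds

    @property
    def null_mean(self) -> float:
        return float(self.null_means.mean())


def permutation_baseline(
    table: pd.DataFrame,
    label_col: str = "condition",
    n_perm: int = 10,
    rf: RFConfig = RFConfig(),
    seed: int = 0,
    features: Sequence[str] | None = None,
    patient_col: str = "patient_id",
    real_cv: CVResult | None = None,
) -> PermutationBaseline:
    """Empirical chance baseline by label permutation.

    The condition labels of the whole table are randomly permuted ``n_perm``
    times (breaking any feature-label association) and the full LOPO
    protocol is re-run on each copy. Returns the null per-fold accuracies
    and a two-sided Wilcoxon rank-sum test of the real per-fold accuracies
    against the pooled null folds.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if real_cv is None:
        real_cv = lopo_cv_rfc(table, label_col, features, rf, seed=int(rng.integers(2**31)), patient_col=patient_col)
    null_scores = []
    for _ in range(n_perm):
        perm = table.copy()
        perm[label_col] = rng.permutation(perm[label_col].to_numpy())
        cv = lopo_cv_rfc(
            perm, label_col, features, rf, seed=int(rng.integers(2**31)),
            patient_col=patient_col, allow_mixed_patients=True,
        )
        null_scores.append(cv.fold_scores)
    null = np.stack(null_scores)
    stat, p = sstats.ranksums(real_cv.fold_scores, null.ravel())
    return PermutationBaseline(
        null_fold_scores=null,
        null_means=null.mean(axis=1),
        real_fold_scores=real_cv.fold_scores,
        wilcoxon_statistic=float(stat),
        p_value=float(p),
    )


def _lopo_subsampled(table, label_col, features, rf, rng, patient_col, train_filter):
    """One LOPO pass where the training set of each fold is reduced by
    ``train_filter(train_df, rng) -> train_df``."""
    feats = list(features) if features is not None else feature_columns(table)
    feats = [f for f in feats if f != label_col]
    patients = sorted(table[patient_col].astype(str).unique())
    scores = []
    for p in patients:
        test = table[patient_col].astype(str) == p
        train = train_filter(table[~test], rng)
        clf = rf.build(rng.integers(2**31))
        clf.fit(train[feats].to_numpy(float), train[label_col].astype(str).to_numpy())
        y_hat = clf.predict(table.loc[test, feats].to_numpy(float))
        scores.append(balanced_accuracy(table.loc[test, label_col].astype(str), y_hat))
    return float(np.mean(scores))


def ablation_patients(
    table: pd.DataFrame,
    label_col: str = "condition",
    k_grid: Sequence[int] = tuple(range(1, 10)),
    reps: int = 10,
    rf: RFConfig = RFConfig(),
    seed: int = 0,
    features: Sequence[str] | None = None,
    patient_col: str = "patient_id",
) -> AblationResult:
    """Learning curve over the number of training patients.

    For each k and each LOPO fold, the forest trains on a random subset of
    k patients per class drawn from the fold's training patients, and is
    evaluated on the held-out patient; the random draw is repeated ``reps``
    times (default 10).
    """
    rng = np.random.default_rng(seed)
    classes = sorted(table[label_col].astype(str).unique())
    class_sizes = table.groupby(label_col)[patient_col].nunique()
    if max(k_grid) > class_sizes.max():
        raise ValueError(
            f"k={max(k_grid)} exceeds the available patients per class ({dict(class_sizes)})"
        )

    def make_filter(k):
        def train_filter(train, rng):
            parts = []
            for c in classes:
                sub = train[train[label_col].astype(str) == c]
                pats = sorted(sub[patient_col].astype(str).unique())
                if k >= len(pats):  # whole class available: identical to standard LOPO
                    parts.append(sub)
                    continue
                chosen = rng.choice(pats, size=k, replace=False)
                parts.append(sub[sub[patient_col].astype(str).isin(chosen)])
            return pd.concat(parts)

        return train_filter

    scores = np.array(
        [
            [
                _lopo_subsampled(table, label_col, features, rf, rng, patient_col, make_filter(k))
                for _ in range(reps)
            ]
            for k in k_grid
        ]
    )
    return AblationResult(grid=list(k_grid), scores=scores)


def ablation_cells(
    table: pd.DataFrame,
    label_col: str = "condition",
    p_grid: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    reps: int = 10,
    rf: RFConfig = RFConfig(),
    seed: int = 0,
    features: Sequence[str] | None = None,
    patient_col: str = "patient_id",
) -> AblationResult:
    """Learning curve over the fraction of cells representing each training
    patient: per patient, ``max(1, floor(p * n))`` cells are kept."""
    rng = np.random.default_rng(seed)

    def make_filter(p):
        def train_filter(train, rng):
            if p >= 1.0:  # full training set: identical to standard LOPO
                return train
            parts = []
            for _, sub in train.groupby(patient_col, sort=True):
                take = max(1, int(np.floor(p * len(sub))))
                parts.append(sub.iloc[np.sort(rng.choice(len(sub), size=take, replace=False))])
            return pd.concat(parts)

        return train_filter

    scores = np.array(
        [
            [
                _lopo_subsampled(table, label_col, features, rf, rng, patient_col, make_filter(p))
                for _ in range(reps)
            ]
            for p in p_grid
        ]
    )
    return AblationResult(grid=list(p_grid), scores=scores)


# ---------------------------------------------------------------------------
# biomarker screens
# ---------------------------------------------------------------------------

def gini_ranking(cv: CVResult, top_n: int = 15, categories: dict[str, str] | None = None) -> pd.DataFrame:
    """Features ranked by mean decrease-in-impurity (Gini) importance
    averaged over the LOPO folds; per-fold importances are normalized to
    sum to 1 by the forest. Returns the ``top_n`` with optional category
    annotation."""
    mean_imp = cv.importances.mean(axis=0)
    order = np.argsort(mean_imp)[::-1][:top_n]
    out = pd.DataFrame(
        {
            "feature": [cv.feature_names[i] for i in order],
            "importance": mean_imp[order],
            "importance_sd": cv.importances.std(axis=0, ddof=0)[order],
        }
    )
    if categories:
        out["category"] = [categories.get(f, "other") for f in out["feature"]]
    return out


def significance_stars(p: float) -> str:
    """Star coding: ns (>0.05), * (<0.05), ** (<0.01), *** (<0.001), **** (<0.0001)."""
    if not np.isfinite(p):
        return "na"
    for cut, code in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < cut:
            return code
    return "ns"


def welch_screen_bh(
    table: pd.DataFrame,
    group_col: str = "condition",
    features: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> ScreenResult:
    """Large-scale per-feature screen: two-sided Welch t-tests between all
    group pairs, Benjamini-Hochberg adjusted across the entire screen;
    significance at adjusted p < ``alpha``. A feature with zero variance in
    both groups of a pair has no defined test and is flagged (NaN p)."""
    feats = list(features) if features is not None else feature_columns(table)
    groups = sorted(table[group_col].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for f in feats:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = table.loc[table[group_col].astype(str) == groups[i], f].dropna().to_numpy(float)
                b = table.loc[table[group_col].astype(str) == groups[j], f].dropna().to_numpy(float)
                if len(a) < 2 or len(b) < 2:
                    raise ValueError(f"feature {f}: need >= 2 cells per group")
                if a.std() == 0 and b.std() == 0:
                    stat, p = np.nan, np.nan
                else:
                    stat, p = sstats.ttest_ind(a, b, equal_var=False)
                rows.append(
                    {
                        "feature": f,
                        "group_a": groups[i],
                        "group_b": groups[j],
                        "statistic": float(stat) if np.isfinite(stat) else np.nan,
                        "p_raw": float(p) if np.isfinite(p) else np.nan,
                        "mean_a": a.mean(),
                        "mean_b": b.mean(),
                        "direction": "a>b" if a.mean() > b.mean() else "a<b",
                    }
                )
    out = pd.DataFrame(rows)
    valid = out["p_raw"].notna()
    out["p_adj"] = np.nan
    if valid.any():
        out.loc[valid, "p_adj"] = multipletests(out.loc[valid, "p_raw"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    out["stars"] = [significance_stars(p) for p in out["p_adj"]]
    return ScreenResult(table=out, alpha=alpha)


def compare_to_control(
    table: pd.DataFrame,
    value_col: str,
    group_col: str = "condition",
    control_label: str = "control",
) -> pd.DataFrame:
    """Control-normalized group comparison of one measured quantity.

    All values are divided by the control group's mean, so the control
    normalized mean is exactly 1. Each non-control group gets a two-sided
    Welch test against control and a significance star code.
    """
    groups = table[group_col].astype(str)
    if control_label not in set(groups):
        raise ValueError(f"control group '{control_label}' not present")
    control = table.loc[groups == control_label, value_col].to_numpy(float)
    cmean = control.mean()
    if cmean == 0:
        raise ValueError("control mean is zero; cannot normalize")
    rows = []
    for g in sorted(groups.unique()):
        vals = table.loc[groups == g, value_col].to_numpy(float) / cmean
        if g == control_label:
            p = np.nan
        else:
            _, p = sstats.ttest_ind(vals, control / cmean, equal_var=False)
        rows.append(
            {
                group_col: g,
                "normalized_mean": vals.mean(),
                "normalized_sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                "n": len(vals),
                "p_vs_control": p,
                "stars": significance_stars(p) if np.isfinite(p) else "",
            }
        )
    return pd.DataFrame(rows)


def qc_embedding(
    table: pd.DataFrame,
    method: str = "tsne",
    seed: int = 0,
    features: Sequence[str] | None = None,
    label_col: str = "condition",
    perplexity: float | None = None,
) -> pd.DataFrame:
    """2-D embedding of the feature table for visual batch-effect QC.

    t-SNE (default) or class-supervised LDA; deterministic under ``seed``.
    Returns one (dim1, dim2) row per cell with the metadata columns
    attached for coloring by patient or condition.
    """
    feats = list(features) if features is not None else feature_columns(table)
    X = table[feats].to_numpy(float)
    n = len(X)
    if method == "tsne":
        perp = perplexity if perplexity is not None else min(30.0, max(5.0, n / 10))
        if n <= perp:
            raise ValueError(f"need more cells than the perplexity ({perp})")
        coords = TSNE(n_components=2, random_state=int(seed), perplexity=perp, init="pca").fit_transform(X)
    elif method == "lda":
        y = table[label_col].astype(str)
        n_comp = min(2, y.nunique() - 1, len(feats))
        lda = LinearDiscriminantAnalysis(n_components=n_comp)
        coords = lda.fit_transform(X, y)
        if coords.shape[1] == 1:  # binary task has a single discriminant axis
            coords = np.column_stack([coords[:, 0], np.zeros(n)])
    else:
        raise ValueError(f"unknown embedding method: {method}")
    out = table[metadata_columns(table)].reset_index(drop=True).copy()
    out["dim1"] = coords[:, 0]
    out["dim2"] = coords[:, 1]
    return out
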