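"""Repeated nested cross-validated linear-SVM classification.

Feature tables are first residualised on dummy-coded site regressors.
Each repetition splits subjects into stratified outer folds; within every
outer training set an inner stratified CV scores each candidate feature
model by balanced accuracy, the winning model is refit on the full outer
training set and evaluated on the held-out validation fold.  Pooled
validation predictions give one balanced accuracy per repetition; the
spread over repetitions yields the 95% CI.  Significance comes from a
permutation null distribution of the same procedure under shuffled labels.

Features are z-scored with training-fold statistics only; the SVM cost is
fixed at 1.  Inner-loop ties are broken by the canonical model order
(:data:`taskconn.measures.MODEL_TAGS`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .cohort import ModuleAssignment
from .measures import MODEL_TAGS, FeatureTable


@dataclass(frozen=True)
class CVConfig:
    outer_folds: int = 10
    inner_folds: int = 5
    repetitions: int = 200
    svm_cost: float = 1.0
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")


@dataclass
class CVResult:
    balanced_accuracies: np.ndarray  # per repetition
    sensitivities: np.ndarray
    specificities: np.ndarray
    aucs: np.ndarray
    mean_balanced_accuracy: float
    ci_lower: float
    ci_upper: float
    model_selection_counts: dict[str, float]  # proportion of inner loops won
    inner_mean_balanced_accuracy: dict[str, float]
    averaged_weights: dict[str, np.ndarray]
    feature_labels: dict[str, list[str]]
    fold_log: list[list[np.ndarray]]  # per rep: validation indices per fold


@dataclass
class PermutationResult:
    null_distribution: np.ndarray
    observed: float
    p_value: float


def site_correct(features: FeatureTable) -> FeatureTable:
    """Residualise every feature column on dummy-coded site regressors.

    With a single site this reduces to column centering.  A site with one
    subject gets a zero residual by construction (warned, not an error).
    """
    sites = features.sites
    counts = sites.value_counts()
    singles = counts[counts == 1]
    if len(singles):
        warnings.warn(f"sites with a single subject: "
                      f"{list(singles.index)}; their residuals are 0",
                      stacklevel=2)
    dummies = pd.get_dummies(sites, drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(sites)), dummies.to_numpy()])
    Y = features.matrix
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    data = pd.DataFrame(resid, index=features.data.index,
                        columns=features.data.columns)
    return replace(features, data=data)


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 with class 1 as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(np.unique(y_true)) < 2:
        raise ValueError("y_true must contain both classes")
    sens = np.mean(y_pred[y_true == 1] == 1)
    spec = np.mean(y_pred[y_true == 0] == 0)
    return (sens + spec) / 2.0


def select_groups(
    models: dict[str, FeatureTable], group_pair: tuple[str, str],
) -> tuple[dict[str, FeatureTable], np.ndarray]:
    """Subset feature tables to two groups; class 1 = first group."""
    pos, neg = group_pair
    any_tab = next(iter(models.values()))
    mask = any_tab.groups.isin([pos, neg])
    if mask.sum() == 0:
        raise ValueError(f"no subjects in groups {group_pair}")
    out = {}
    for tag, tab in models.items():
        out[tag] = replace(tab, data=tab.data.loc[mask],
                           groups=tab.groups.loc[mask],
                           sites=tab.sites.loc[mask])
    y = (any_tab.groups.loc[mask] == pos).to_numpy().astype(int)
    return out, y


def _zscore_train(train: np.ndarray, other: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd


def _check_stratifiable(y: np.ndarray, config: CVConfig) -> None:
    n_min = np.bincount(y).min()
    if n_min < config.outer_folds:
        raise ValueError(
            f"smallest class has {n_min} members < outer_folds="
            f"{config.outer_folds}; use fewer folds")
    inner_min = n_min - int(np.ceil(n_min / config.outer_folds))
    if inner_min < config.inner_folds:
        raise ValueError(
            f"smallest class leaves {inner_min} members for the inner loop "
            f"< inner_folds={config.inner_folds}; use fewer folds")


def _ordered_tags(models: dict[str, FeatureTable]) -> list[str]:
    ordered = [t for t in MODEL_TAGS if t in models]
    ordered += [t for t in models if t not in MODEL_TAGS]
    return ordered


def nested_cv_classify(
    models: dict[str, FeatureTable],
    labels: np.ndarray,
    config: CVConfig = CVConfig(),
) -> CVResult:
    """Repeated nested CV with inner-loop feature-model selection."""
    if not models:
        raise ValueError("no feature models supplied")
    y = np.asarray(labels).astype(int)
    tags = _ordered_tags(models)
    X = {t: models[t].matrix for t in tags}
    n = len(y)
    for t in tags:
        if X[t].shape[0] != n:
            raise ValueError(f"model {t!r} rows misaligned with labels")
    _check_stratifiable(y, config)

    rep_bas, rep_sens, rep_spec, rep_auc = [], [], [], []
    win_counts = {t: 0 for t in tags}
    inner_scores: dict[str, list[float]] = {t: [] for t in tags}
    weight_sums = {t: np.zeros(X[t].shape[1]) for t in tags}
    fold_log: list[list[np.ndarray]] = []

    base = np.random.SeedSequence(config.seed)
    rep_seeds = base.spawn(config.repetitions)
    for rep, seq in enumerate(rep_seeds):
        rs = int(seq.generate_state(1)[0] % 2**31)
        outer = StratifiedKFold(config.outer_folds, shuffle=True,
                                random_state=rs)
        y_pred = np.empty(n, dtype=int)
        y_dec = np.empty(n, dtype=float)
        rep_folds = []
        for f, (tr, va) in enumerate(outer.split(np.zeros(n), y)):
            rep_folds.append(va)
            inner = StratifiedKFold(config.inner_folds, shuffle=True,
                                    random_state=rs + f + 1)
            best_tag, best_ba = None, -np.inf
            for t in tags:
                preds = np.empty(len(tr), dtype=int)
                for itr, iva in inner.split(np.zeros(len(tr)), y[tr]):
                    Xtr, Xva = _zscore_train(X[t][tr[itr]], X[t][tr[iva]])
                    clf = LinearSVC(C=config.svm_cost, random_state=0)
                    clf.fit(Xtr, y[tr[itr]])
                    preds[iva] = clf.predict(Xva)
                ba = balanced_accuracy(y[tr], preds)
                inner_scores[t].append(ba)
                if ba > best_ba:  # strict: ties keep earlier canonical tag
                    best_tag, best_ba = t, ba
            win_counts[best_tag] += 1
            Xtr, Xva = _zscore_train(X[best_tag][tr], X[best_tag][va])
            clf = LinearSVC(C=config.svm_cost, random_state=0)
            clf.fit(Xtr, y[tr])
            y_pred[va] = clf.predict(Xva)
            y_dec[va] = clf.decision_function(Xva)
            weight_sums[best_tag] += clf.coef_.ravel()
        fold_log.append(rep_folds)
        rep_bas.append(balanced_accuracy(y, y_pred))
        rep_sens.append(float(np.mean(y_pred[y == 1] == 1)))
        rep_spec.append(float(np.mean(y_pred[y == 0] == 0)))
        rep_auc.append(float(roc_auc_score(y, y_dec)))

    bas = np.array(rep_bas)
    total_wins = sum(win_counts.values())
    avg_w = {t: weight_sums[t] / win_counts[t]
             for t in tags if win_counts[t] > 0}
    return CVResult(
        balanced_accuracies=bas,
        sensitivities=np.array(rep_sens),
        specificities=np.array(rep_spec),
        aucs=np.array(rep_auc),
        mean_balanced_accuracy=float(bas.mean()),
        ci_lower=float(np.percentile(bas, 2.5)),
        ci_upper=float(np.percentile(bas, 97.5)),
        model_selection_counts={t: win_counts[t] / total_wins for t in tags},
        inner_mean_balanced_accuracy={
            t: float(np.mean(v)) for t, v in inner_scores.items()},
        averaged_weights=avg_w,
        feature_labels={t: models[t].feature_labels for t in tags},
        fold_log=fold_log,
    )


def permutation_test(
    models: dict[str, FeatureTable],
    labels: np.ndarray,
    config: CVConfig = CVConfig(),
    observed: float | None = None,
) -> PermutationResult:
    """Permutation null of the nested-CV balanced accuracy.

    Each permutation shuffles the labels once and scores a single
    nested-CV pass (repetitions = 1); the p-value is the fraction of null
    balanced accuracies at or above the observed mean, clipped below at
    1 / n_permutations.
    """
    y = np.asarray(labels).astype(int)
    if observed is None:
        observed = nested_cv_classify(models, y, config).mean_balanced_accuracy
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x9E)))
    null = np.empty(config.n_permutations)
    one_rep = replace(config, repetitions=1)
    for b in range(config.n_permutations):
        perm = rng.permutation(len(y))
        res = nested_cv_classify(models, y[perm],
                                 replace(one_rep, seed=config.seed + b + 1))
        null[b] = res.mean_balanced_accuracy
    p = max(float(np.mean(null >= observed)), 1.0 / config.n_permutations)
    return PermutationResult(null_distribution=null, observed=float(observed),
                             p_value=p)


def rank_weights(result: CVResult, model_tag: str) -> list[tuple[str, float, int]]:
    """Features of one model sorted by |averaged weight| (sign retained)."""
    if model_tag not in result.averaged_weights:
        raise KeyError(f"model {model_tag!r} never won an inner loop; "
                       f"no averaged weights available")
    w = result.averaged_weights[model_tag]
    labels = result.feature_labels[model_tag]
    order = np.argsort(-np.abs(w), kind="stable")
    return [(labels[i], float(w[i]), r + 1) for r, i in enumerate(order)]


def module_group_test(
    features: FeatureTable,
    modules: ModuleAssignment,
    group_pair: tuple[str, str],
) -> pd.DataFrame:
    """Per-module group contrast of a node measure.

    Each subject's measure is averaged over the module's nodes; groups are
    compared with Welch's t-test and Cohen's d (pooled SD).
    """
    g1, g2 = group_pair
    rows = {}
    for mod in modules.modules:
        nodes = [n for n in modules.nodes_of(mod)
                 if n in features.data.columns]
        if not nodes:
            raise ValueError(f"module {mod!r} has no nodes in the table")
        per_subject = features.data[nodes].mean(axis=1)
        a = per_subject[features.groups == g1].to_numpy()
        b = per_subject[features.groups == g2].to_numpy()
        t, p = stats.ttest_ind(a, b, equal_var=False)
        pooled = np.sqrt(((len(a) - 1) * a.var(ddof=1)
                          + (len(b) - 1) * b.var(ddof=1))
                         / (len(a) + len(b) - 2))
        d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
        rows[mod] = {"cohens_d": d, "t": float(t), "p": float(p)}
    return pd.DataFrame.from_dict(rows, orient="index")


def subsampling_curve(
    models: dict[str, FeatureTable],
    labels: np.ndarray,
    sizes: list[int],
    config: CVConfig = CVConfig(),
    n_draws: int = 5,
) -> pd.DataFrame:
    """Mean balanced accuracy at stratified subsample sizes (learning curve)."""
    y = np.asarray(labels).astype(int)
    n = len(y)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x5B)))
    idx1, idx0 = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    ratio = len(idx1) / n
    rows = []
    for size in sizes:
        if size > n:
            raise ValueError(f"subsample size {size} exceeds n={n}")
        n1 = int(round(size * ratio))
        n0 = size - n1
        bas = []
        draws = 1 if size == n else n_draws
        for d in range(draws):
            if size == n:
                sel = np.arange(n)
            else:
                sel = np.concatenate([rng.choice(idx1, n1, replace=False),
                                      rng.choice(idx0, n0, replace=False)])
            sub = {t: replace(tab, data=tab.data.iloc[sel],
                              groups=tab.groups.iloc[sel],
                              sites=tab.sites.iloc[sel])
                   for t, tab in models.items()}
            res = nested_cv_classify(sub, y[sel],
                                     replace(config, seed=config.seed + d))
            bas.append(res.mean_balanced_accuracy)
        rows.append({"size": size, "mean_balanced_accuracy": np.mean(bas),
                     "ci_lower": np.percentile(bas, 2.5),
                     "ci_upper": np.percentile(bas, 97.5)})
    return pd.DataFrame(rows).set_index("size")
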