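"""Kernel-based decoding-relevance framework.

Human-face versus non-face classification from windowed band-power time
courses, used to assess which sites carry face information:

* model I — all temporal-cortex sites;
* model II — all sites except the human-face-selective ones;
* model IIIa — face-selective sites only (task-active removed);
* model III — an ensemble of 499 random site subsets of model II's
  size, each containing at least one face-selective site, relating
  accuracy to the proportion of face sites included;
* model IV — sparse multiple kernel learning with one linear kernel per
  site, yielding a per-site contribution map;
* band kernels — the same sparse combination over frequency-band
  kernels.

Features are the concatenated per-site time courses in the
[150, 500) ms window; classification uses a soft-margin SVM on the
linear (dot-product) kernel with nested stratified cross-validation
(5 outer folds; 4 inner folds select C from {0.01, 0.1, 1, 10, 100}).
Performance is balanced accuracy, the mean of the two class
sensitivities; significance comes from label permutations within the
same CV structure.  Non-face trials (7 subcategories) are subsampled to
match the face count before modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import NONFACE_CATEGORIES, BandPowerEpochs

__all__ = [
    "CVConfig",
    "DecodingResult",
    "ContributionMap",
    "subsample_nonfaces",
    "linear_kernel",
    "balanced_accuracy",
    "crossval_svm",
    "permutation_significance",
    "build_features",
    "run_site_set_model",
    "random_set_models",
    "sparse_mkl",
    "contribution_selectivity_correlation",
]

C_GRID_DEFAULT: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings.

    ``inner_folds=0`` disables the inner C search and uses ``c_fixed``
    (the reduced setting for large model ensembles).
    """

    outer_folds: int = 5
    inner_folds: int = 4
    c_grid: tuple[float, ...] = C_GRID_DEFAULT
    c_fixed: float = 1.0


@dataclass
class DecodingResult:
    balanced_accuracy: float  # percent
    fold_metrics: list[dict]  # per fold: sensitivities, chosen C, confusion
    model: str = ""
    p_permutation: float = float("nan")
    n_epochs: int = 0

    @property
    def sensitivities(self) -> tuple[float, float]:
        s0 = float(np.mean([f["sens_class0"] for f in self.fold_metrics]))
        s1 = float(np.mean([f["sens_class1"] for f in self.fold_metrics]))
        return s0, s1


@dataclass
class ContributionMap:
    """Non-negative per-kernel contributions (summing to 1 when any is
    non-zero) and the resulting sparsity = fraction of non-null
    contributions."""

    names: list[str]
    contributions: np.ndarray
    sparsity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"kernel": self.names, "contribution": self.contributions})


def subsample_nonfaces(
    categories: np.ndarray,
    target: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Indices of non-face trials subsampled to (approximately) the
    face-trial count, drawing as evenly as possible from the 7 non-face
    subcategories (per-subcategory sizes differ by at most one unless a
    subcategory runs short; the total is within one of ``target``)."""
    categories = np.asarray(categories)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub_idx = {c: np.flatnonzero(categories == c) for c in NONFACE_CATEGORIES}
    for c, idx in sub_idx.items():
        if len(idx) == 0:
            raise ValueError(f"non-face subcategory {c!r} has no trials")
    total_avail = sum(len(v) for v in sub_idx.values())
    if target > total_avail:
        raise ValueError(f"target {target} exceeds available non-face trials {total_avail}")
    n_sub = len(NONFACE_CATEGORIES)
    base, rem = divmod(target, n_sub)
    quotas = {c: base for c in NONFACE_CATEGORIES}
    extra = rng.choice(list(NONFACE_CATEGORIES), size=rem, replace=False)
    for c in extra:
        quotas[c] += 1
    # redistribute any shortfall to subcategories with spare trials
    short = 0
    for c in NONFACE_CATEGORIES:
        if quotas[c] > len(sub_idx[c]):
            short += quotas[c] - len(sub_idx[c])
            quotas[c] = len(sub_idx[c])
    while short > 0:
        spare = [c for c in NONFACE_CATEGORIES if quotas[c] < len(sub_idx[c])]
        c = spare[0]
        quotas[c] += 1
        short -= 1
    chosen = [rng.choice(sub_idx[c], size=quotas[c], replace=False) for c in NONFACE_CATEGORIES]
    return np.sort(np.concatenate(chosen))


def linear_kernel(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Dot-product similarity matrix between epochs (rows)."""
    a = np.asarray(a, dtype=float)
    b = a if b is None else np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions do not match")
    return a @ b.T


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(balanced accuracy, sensitivity class 0, sensitivity class 1),
    balanced accuracy being the mean of the two sensitivities."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    if len(classes) != 2:
        raise ValueError("balanced accuracy is defined for two classes")
    s = [float(np.mean(y_pred[y_true == c] == c)) for c in classes]
    return (s[0] + s[1]) / 2.0, s[0], s[1]


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator):
    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    return list(skf.split(np.zeros(len(labels)), labels))


def _fit_predict(K: np.ndarray, labels, train, test, c: float) -> np.ndarray:
    svc = SVC(C=c, kernel="precomputed")
    svc.fit(K[np.ix_(train, train)], labels[train])
    return svc.predict(K[np.ix_(test, train)])


def crossval_svm(
    K: np.ndarray,
    labels: np.ndarray,
    cv: CVConfig = CVConfig(),
    seed: int | np.random.Generator = 0,
    *,
    model: str = "",
    folds=None,
) -> DecodingResult:
    """Nested stratified cross-validation of a precomputed-kernel SVM.

    Outer folds are disjoint and label-stratified; within each outer
    training set, an inner stratified CV selects the soft-margin C by
    balanced accuracy (ties broken toward the smallest, i.e. most
    regularized, C).  Reported performance is the mean over outer folds
    of the test balanced accuracy, in percent.
    """
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if folds is None:
        folds = _stratified_folds(labels, cv.outer_folds, rng)
    fold_metrics = []
    for train, test in folds:
        if cv.inner_folds >= 2:
            inner = _stratified_folds(labels[train], cv.inner_folds, rng)
            best_c, best_acc = cv.c_grid[0], -1.0
            for c in cv.c_grid:
                accs = []
                for itr, ite in inner:
                    pred = _fit_predict(K[np.ix_(train, train)], labels[train], itr, ite, c)
                    accs.append(balanced_accuracy(labels[train][ite], pred)[0])
                mean_acc = float(np.mean(accs))
                if mean_acc > best_acc + 1e-12:
                    best_acc, best_c = mean_acc, c
        else:
            best_c = cv.c_fixed
        pred = _fit_predict(K, labels, train, test, best_c)
        bacc, s0, s1 = balanced_accuracy(labels[test], pred)
        fold_metrics.append(
            {"balanced_accuracy": bacc, "sens_class0": s0, "sens_class1": s1, "C": best_c}
        )
    mean_bacc = 100.0 * float(np.mean([f["balanced_accuracy"] for f in fold_metrics]))
    return DecodingResult(
        balanced_accuracy=mean_bacc,
        fold_metrics=fold_metrics,
        model=model,
        n_epochs=len(labels),
    )


def permutation_significance(
    K: np.ndarray,
    labels: np.ndarray,
    observed_accuracy: float,
    n_perm: int = 1000,
    cv: CVConfig = CVConfig(),
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value of a decoding accuracy: labels are permuted
    and the full CV pipeline re-run; p = (1 + #{null >= observed}) /
    (n_perm + 1)."""
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels)
        null[i] = crossval_svm(K, perm, cv, rng).balanced_accuracy
    k = int(np.sum(null >= observed_accuracy - 1e-12))
    return (k + 1) / (n_perm + 1)


def build_features(
    bp: BandPowerEpochs,
    sites: list[str],
    epoch_idx: np.ndarray,
    *,
    window_ms: tuple[float, float] = (150.0, 500.0),
) -> np.ndarray:
    """Epochs-by-features matrix: per-site band-power time courses in
    the analysis window, concatenated across sites (feature count =
    n_sites x window samples)."""
    if not sites:
        raise ValueError("site set is empty")
    sub = bp.select_channels(sites)
    tmask = sub.time_mask(window_ms)
    x = sub.data[np.ix_(epoch_idx, np.arange(len(sites)), np.flatnonzero(tmask))]
    return x.reshape(len(epoch_idx), -1)


def _face_nonface_epochs(bp: BandPowerEpochs, rng: np.random.Generator):
    """Balanced epoch selection: all human-face trials plus matched
    subsampled non-face trials; returns (epoch indices, labels)."""
    face_idx = np.flatnonzero(bp.categories == "human_face")
    if len(face_idx) == 0:
        raise ValueError("no human-face trials")
    nonface_idx = subsample_nonfaces(bp.categories, len(face_idx), rng)
    idx = np.concatenate([face_idx, nonface_idx])
    labels = np.array(["face"] * len(face_idx) + ["nonface"] * len(nonface_idx))
    return idx, labels


def run_site_set_model(
    bp: BandPowerEpochs,
    sites: list[str],
    seed: int | np.random.Generator = 0,
    *,
    window_ms: tuple[float, float] = (150.0, 500.0),
    cv: CVConfig = CVConfig(),
    model: str = "",
    n_perm: int = 0,
) -> DecodingResult:
    """Face / non-face decoding from one site set (models I, II, IIIa):
    subsample non-faces, build the linear kernel over windowed features,
    run the nested CV, and optionally assess permutation significance."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx, labels = _face_nonface_epochs(bp, rng)
    X = build_features(bp, sites, idx, window_ms=window_ms)
    K = linear_kernel(X)
    res = crossval_svm(K, labels, cv, rng, model=model)
    if n_perm > 0:
        res.p_permutation = permutation_significance(
            K, labels, res.balanced_accuracy, n_perm, cv, rng
        )
    return res


@dataclass
class RandomSetResult:
    accuracies: np.ndarray
    face_proportions: np.ndarray
    rho: float
    p: float
    site_sets: list[list[str]]


def random_set_models(
    bp: BandPowerEpochs,
    face_sites: list[str],
    task_sites: list[str],
    *,
    n_models: int = 499,
    size: int | None = None,
    seed: int | np.random.Generator = 0,
    window_ms: tuple[float, float] = (150.0, 500.0),
    cv: CVConfig = CVConfig(inner_folds=0),
) -> RandomSetResult:
    """Random-subset ensemble (model III): ``n_models`` site sets of the
    model-II size drawn without replacement from face + task-active
    sites, each constrained to contain at least one face site.  Returns
    per-model accuracy, the proportion of face sites, and their Spearman
    correlation.

    The ensemble shares one non-face subsample and one fold structure
    across models so that only the site sets differ.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not face_sites:
        raise ValueError("need at least one face-selective site")
    pool = list(face_sites) + list(task_sites)
    if size is None:
        size = max(len(pool) - len(face_sites), 1)
    if size > len(pool):
        raise ValueError("requested set size exceeds the available sites")
    idx, labels = _face_nonface_epochs(bp, rng)
    folds = _stratified_folds(labels, cv.outer_folds, rng)
    accuracies = np.empty(n_models)
    proportions = np.empty(n_models)
    site_sets: list[list[str]] = []
    for m in range(n_models):
        while True:
            chosen = list(rng.choice(pool, size=size, replace=False))
            n_face = sum(s in face_sites for s in chosen)
            if n_face >= 1:
                break
        X = build_features(bp, chosen, idx, window_ms=window_ms)
        K = linear_kernel(X)
        res = crossval_svm(K, labels, cv, rng, folds=folds)
        accuracies[m] = res.balanced_accuracy
        proportions[m] = n_face / size
        site_sets.append(chosen)
    if np.ptp(proportions) == 0 or np.ptp(accuracies) == 0:
        rho, p = float("nan"), float("nan")
    else:
        rho, p = stats.spearmanr(accuracies, proportions)
    return RandomSetResult(
        accuracies=accuracies,
        face_proportions=proportions,
        rho=float(rho),
        p=float(p),
        site_sets=site_sets,
    )


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho_idx = np.flatnonzero(u * np.arange(1, len(v) + 1) > css - 1.0)
    if len(rho_idx) == 0:
        out = np.zeros_like(v)
        out[np.argmax(v)] = 1.0
        return out
    r = rho_idx[-1]
    theta = (css[r] - 1.0) / (r + 1)
    return np.maximum(v - theta, 0.0)


def _svm_objective_and_grad(
    kernels: list[np.ndarray], d: np.ndarray, labels01: np.ndarray, c: float
):
    """Fit the SVM on the combined kernel and return (objective,
    gradient wrt the kernel weights).  For the SVM dual J(d) =
    sum(alpha) - 1/2 a' K a with a = y*alpha, dJ/dd_m = -1/2 a' K_m a."""
    K = sum(w * Km for w, Km in zip(d, kernels))
    svc = SVC(C=c, kernel="precomputed")
    svc.fit(K, labels01)
    sv = svc.support_
    a = svc.dual_coef_[0]  # y_i * alpha_i over support vectors
    obj = float(np.abs(a).sum() - 0.5 * a @ K[np.ix_(sv, sv)] @ a)
    grad = np.array([-0.5 * a @ Km[np.ix_(sv, sv)] @ a for Km in kernels])
    return obj, grad, svc


def _mkl_fit(
    kernels: list[np.ndarray],
    labels01: np.ndarray,
    c: float,
    *,
    max_iter: int = 200,
    tol: float = 1e-4,
    step: float = 1.0,
):
    """Sparse multiple kernel learning by projected-gradient descent of
    the max-margin objective over the kernel-weight simplex (the
    simplex constraint is the L1 prior that zeroes out kernels)."""
    m = len(kernels)
    d = np.full(m, 1.0 / m)
    obj, grad, svc = _svm_objective_and_grad(kernels, d, labels01, c)
    converged = False
    for _ in range(max_iter):
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-15:
            converged = True
            break
        eta = step
        improved = False
        for _ in range(12):
            d_new = _project_simplex(d - eta * grad / gnorm)
            obj_new, grad_new, svc_new = _svm_objective_and_grad(
                kernels, d_new, labels01, c
            )
            if obj_new < obj - 1e-12:
                improved = True
                break
            eta *= 0.5
        if not improved:
            converged = True
            break
        delta = np.abs(d_new - d).max()
        d, obj, grad, svc = d_new, obj_new, grad_new, svc_new
        if delta < tol:
            converged = True
            break
    return d, svc, converged


def sparse_mkl(
    kernels: dict[str, np.ndarray] | list[np.ndarray],
    labels: np.ndarray,
    cv: CVConfig = CVConfig(),
    seed: int | np.random.Generator = 0,
    *,
    trace_normalize: bool = True,
    max_iter: int = 200,
    tol: float = 1e-4,
    model: str = "IV",
) -> tuple[DecodingResult, ContributionMap]:
    """Sparse multiple-kernel decoding (model IV; also band kernels).

    One linear kernel per site (or band) is combined through a learned
    convex combination constrained to the simplex, wrapped around the
    same soft-margin SVM; many weights shrink to exactly zero, giving a
    per-kernel contribution map and a sparsity (fraction of non-null
    contributions, computed per fold and averaged).  Kernels are
    trace-normalized by default so high-variance sites do not dominate.
    Non-convergence within ``max_iter`` is flagged on the result model
    name ("<model>:partial").
    """
    if isinstance(kernels, dict):
        names = list(kernels.keys())
        mats = [np.asarray(kernels[n], dtype=float) for n in names]
    else:
        mats = [np.asarray(k, dtype=float) for k in kernels]
        names = [f"k{i}" for i in range(len(mats))]
    if len(mats) < 1:
        raise ValueError("need at least one kernel")
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(labels)
    if trace_normalize:
        mats = [K * (n / max(np.trace(K), 1e-12)) for K in mats]
    folds = _stratified_folds(labels, cv.outer_folds, rng)
    classes = np.unique(labels)
    fold_metrics = []
    weights = np.zeros((len(folds), len(mats)))
    sparsities = []
    all_converged = True
    c_choice = cv.c_fixed if cv.inner_folds < 2 else 1.0
    for fi, (train, test) in enumerate(folds):
        sub = [K[np.ix_(train, train)] for K in mats]
        if cv.inner_folds >= 2:
            inner = _stratified_folds(labels[train], cv.inner_folds, rng)
            best_c, best_acc = cv.c_grid[0], -1.0
            for c in cv.c_grid:
                accs = []
                for itr, ite in inner:
                    d_i, _, _ = _mkl_fit(
                        [K[np.ix_(itr, itr)] for K in sub],
                        labels[train][itr],
                        c,
                        max_iter=max_iter // 4,
                        tol=tol * 10,
                    )
                    Ki = sum(w * K for w, K in zip(d_i, sub))
                    svc = SVC(C=c, kernel="precomputed")
                    svc.fit(Ki[np.ix_(itr, itr)], labels[train][itr])
                    pred = svc.predict(Ki[np.ix_(ite, itr)])
                    accs.append(balanced_accuracy(labels[train][ite], pred)[0])
                mean_acc = float(np.mean(accs))
                if mean_acc > best_acc + 1e-12:
                    best_acc, best_c = mean_acc, c
            c_choice = best_c
        d, _, converged = _mkl_fit(sub, labels[train], c_choice, max_iter=max_iter, tol=tol)
        all_converged &= converged
        Kcomb = sum(w * K for w, K in zip(d, mats))
        svc = SVC(C=c_choice, kernel="precomputed")
        svc.fit(Kcomb[np.ix_(train, train)], labels[train])
        pred = svc.predict(Kcomb[np.ix_(test, train)])
        bacc, s0, s1 = balanced_accuracy(labels[test], pred)
        fold_metrics.append(
            {"balanced_accuracy": bacc, "sens_class0": s0, "sens_class1": s1, "C": c_choice}
        )
        weights[fi] = d
        sparsities.append(float(np.mean(d > 1e-8)))
    contrib = weights.mean(axis=0)
    contrib[contrib < 1e-8] = 0.0
    total = contrib.sum()
    if total > 0:
        contrib = contrib / total
    result = DecodingResult(
        balanced_accuracy=100.0 * float(np.mean([f["balanced_accuracy"] for f in fold_metrics])),
        fold_metrics=fold_metrics,
        model=model if all_converged else f"{model}:partial",
        n_epochs=n,
    )
    cmap = ContributionMap(
        names=names, contributions=contrib, sparsity=float(np.mean(sparsities))
    )
    return result, cmap


def contribution_selectivity_correlation(
    contributions: np.ndarray, selectivity: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between per-site model contributions and
    human-face selectivity scores."""
    contributions = np.asarray(contributions, dtype=float)
    selectivity = np.asarray(selectivity, dtype=float)
    if contributions.shape != selectivity.shape:
        raise ValueError("site lists are not aligned")
    r, p = stats.pearsonr(contributions, selectivity)
    return float(r), float(p)
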