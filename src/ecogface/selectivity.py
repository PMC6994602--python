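"""Permutation-based univariate site classification.

A site (electrode) is "active" if its high-frequency broadband response
in the [150, 500) ms analysis window differs from its own pre-stimulus
baseline for at least one category (paired sign-flip permutation test,
FDR-corrected over sites).  Among active sites, "face-selective" sites
respond more to the four pooled face categories than to pooled
non-faces, and "human-face-selective" sites respond more to human faces
than to pooled non-faces (one-sided label-shuffle permutation tests,
FDR-corrected over sites).  Active sites that are neither are
"task-active".  The selectivity score of a site is its mean windowed
response to human faces minus that to pooled non-faces, in dB.

Randomness: each (site, contrast) test draws its permutations from an
independent stream spawned from the master seed by a counter, so
results do not depend on the order in which sites are tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import (
    CATEGORIES,
    FACE_CATEGORIES,
    NONFACE_CATEGORIES,
    BandPowerEpochs,
)

__all__ = [
    "PermTestResult",
    "SiteClassification",
    "permutation_test_paired",
    "permutation_test_unpaired",
    "fdr_bh",
    "classify_sites",
    "compare_face_subcategories",
    "band_scan",
]


@dataclass(frozen=True)
class PermTestResult:
    observed: float
    n_perm: int
    p: float
    paired: bool
    alternative: str  # "two-sided" | "greater"


def _p_from_null(null: np.ndarray, observed: float, alternative: str) -> float:
    """(k+1)/(N+1) permutation p-value estimator (never exactly zero);
    a small tolerance keeps tied null values (recomputed in a different
    summation order) on the rejection side."""
    eps = 1e-9 * max(1.0, abs(observed))
    if alternative == "two-sided":
        k = int(np.sum(np.abs(null) >= abs(observed) - eps))
    elif alternative == "greater":
        k = int(np.sum(null >= observed - eps))
    else:
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    return (k + 1) / (len(null) + 1)


def permutation_test_paired(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 50_000,
    *,
    alternative: str = "two-sided",
    rng: np.random.Generator | int | None = None,
    exhaustive_max: int = 0,
) -> PermTestResult:
    """Paired permutation test on the mean difference.

    The null distribution is built by random sign flips of the per-pair
    differences.  With ``exhaustive_max >= len(x)`` all 2^n sign
    patterns are enumerated instead (then p = k / 2^n exactly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    obs = float(d.mean())
    n = len(d)
    if exhaustive_max and n <= exhaustive_max:
        signs = np.array(
            [[1 if (i >> b) & 1 else -1 for b in range(n)] for i in range(2**n)],
            dtype=float,
        )
        null = signs @ d / n
        if alternative == "two-sided":
            p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
        else:
            p = float(np.mean(null >= obs - 1e-12))
        return PermTestResult(obs, 2**n, p, True, alternative)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if n_perm < 1000:
        raise ValueError("use at least 1000 permutations")
    # sorted differences: the null is exchangeable, and sorting makes the
    # Monte-Carlo draw invariant to trial ordering
    signs = gen.choice([-1.0, 1.0], size=(n_perm, n))
    null = signs @ np.sort(d) / n
    return PermTestResult(obs, n_perm, _p_from_null(null, obs, alternative), True, alternative)


def permutation_test_unpaired(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    *,
    alternative: str = "two-sided",
    rng: np.random.Generator | int | None = None,
    exhaustive_max: int = 0,
) -> PermTestResult:
    """Unpaired permutation test on the difference of group means; the
    null is built by shuffling group labels.  With ``exhaustive_max``
    at least the total sample size, all label assignments are
    enumerated."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n_a, n_tot = len(a), len(pooled)
    obs = float(a.mean() - b.mean())
    if exhaustive_max and n_tot <= exhaustive_max:
        null = np.array(
            [
                pooled[list(idx)].mean()
                - np.delete(pooled, list(idx)).mean()
                for idx in combinations(range(n_tot), n_a)
            ]
        )
        if alternative == "two-sided":
            p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
        else:
            p = float(np.mean(null >= obs - 1e-12))
        return PermTestResult(obs, len(null), p, False, alternative)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    # vectorized label shuffles: argsort of random keys = random
    # permutations; pooled values sorted so the draw does not depend on
    # input ordering
    keys = gen.random((n_perm, n_tot))
    idx = np.argsort(keys, axis=1)
    perm = np.sort(pooled)[idx]
    null = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
    return PermTestResult(obs, n_perm, _p_from_null(null, obs, alternative), False, alternative)


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class SiteClassification:
    """Per-site classification table.

    Columns: name, y, mean response per category (dB, analysis window),
    p_active, p_face, p_human_face, active, face_selective,
    human_face_selective, task_active, selectivity.
    """

    table: pd.DataFrame
    window_ms: tuple[float, float]
    q: float

    def sites(self, flag: str) -> list[str]:
        return list(self.table.loc[self.table[flag], "name"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _spawned_rng(master_seed: int, *counters) -> np.random.Generator:
    """Independent stream per (contrast, site): string keys are hashed
    stably so results do not depend on channel ordering."""
    from zlib import crc32

    key = tuple(
        crc32(c.encode()) if isinstance(c, str) else int(c) for c in counters
    )
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def classify_sites(
    bp: BandPowerEpochs,
    *,
    window_ms: tuple[float, float] = (150.0, 500.0),
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
    n_perm_active: int = 50_000,
    n_perm_selective: int = 10_000,
    q: float = 0.05,
    seed: int = 0,
    activity_alternative: str = "two-sided",
) -> SiteClassification:
    """Classify every site as active / face-selective /
    human-face-selective / task-active.

    Activity: per category, the windowed mean response of each trial is
    compared to that trial's baseline mean (paired sign-flip test);
    FDR is applied across sites within each category, and a site is
    active if any category survives.  Selectivity contrasts are
    one-sided unpaired tests of pooled faces (or human faces) against
    pooled non-faces, FDR-corrected across sites, and are assessed
    among active sites only.
    """
    cats_present = set(bp.categories)
    missing = set(CATEGORIES) - cats_present
    if missing:
        raise ValueError(f"missing categories: {sorted(missing)}")
    resp = bp.windowed_mean(window_ms)  # (trials, sites)
    base = bp.windowed_mean(baseline_ms)
    n_sites = len(bp.channel_names)
    cats = bp.categories

    p_active_per_cat = np.empty((len(CATEGORIES), n_sites))
    for ci, cat in enumerate(CATEGORIES):
        tmask = cats == cat
        for si in range(n_sites):
            r = permutation_test_paired(
                resp[tmask, si],
                base[tmask, si],
                n_perm_active,
                alternative=activity_alternative,
                rng=_spawned_rng(seed, 0, ci, bp.channel_names[si]),
            )
            p_active_per_cat[ci, si] = r.p
    active = np.zeros(n_sites, dtype=bool)
    for ci in range(len(CATEGORIES)):
        active |= fdr_bh(p_active_per_cat[ci], q)
    p_active = p_active_per_cat.min(axis=0)

    face_mask = np.isin(cats, FACE_CATEGORIES)
    human_mask = cats == "human_face"
    nonface_mask = np.isin(cats, NONFACE_CATEGORIES)
    p_face = np.empty(n_sites)
    p_human = np.empty(n_sites)
    for si in range(n_sites):
        p_face[si] = permutation_test_unpaired(
            resp[face_mask, si],
            resp[nonface_mask, si],
            n_perm_selective,
            alternative="greater",
            rng=_spawned_rng(seed, 1, bp.channel_names[si]),
        ).p
        p_human[si] = permutation_test_unpaired(
            resp[human_mask, si],
            resp[nonface_mask, si],
            n_perm_selective,
            alternative="greater",
            rng=_spawned_rng(seed, 2, bp.channel_names[si]),
        ).p
    face_sel = fdr_bh(p_face, q) & active
    human_sel = fdr_bh(p_human, q) & active
    task_active = active & ~face_sel & ~human_sel
    selectivity = (
        resp[human_mask].mean(axis=0) - resp[nonface_mask].mean(axis=0)
    )

    rows: dict = {"name": bp.channel_names}
    if bp.layout is not None:
        ymap = dict(zip(bp.layout.table["name"], bp.layout.table["y"]))
        rows["y"] = [ymap.get(n, np.nan) for n in bp.channel_names]
    else:
        rows["y"] = np.nan
    for ci, cat in enumerate(CATEGORIES):
        rows[f"mean_{cat}"] = resp[cats == cat].mean(axis=0)
    rows.update(
        p_active=p_active,
        p_face=p_face,
        p_human_face=p_human,
        active=active,
        face_selective=face_sel,
        human_face_selective=human_sel,
        task_active=task_active,
        selectivity=selectivity,
    )
    return SiteClassification(table=pd.DataFrame(rows), window_ms=window_ms, q=q)


def compare_face_subcategories(
    bp: BandPowerEpochs,
    sites: list[str],
    other_sites: list[str] | None = None,
    *,
    window_ms: tuple[float, float] = (150.0, 500.0),
    n_perm: int = 10_000,
    q: float = 0.05,
    seed: int = 0,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Pairwise comparison of the four face subcategories (6 pairs) on
    the mean windowed response pooled over a site subset.

    When a second subset is given (face-selective and task-active sets),
    all 12 tests enter one FDR family, matching the correction over
    6 + 6 comparisons.  Returns a table with columns site_set, cat_a,
    cat_b, observed, p, significant.
    """
    if not sites:
        raise ValueError("site subset is empty")
    site_sets = {"set1": sites}
    if other_sites:
        site_sets["set2"] = other_sites
    rows = []
    counter = 0
    for set_name, subset in site_sets.items():
        sub = bp.select_channels(subset)
        resp = sub.windowed_mean(window_ms).mean(axis=1)  # pooled over sites
        for cat_a, cat_b in combinations(FACE_CATEGORIES, 2):
            res = permutation_test_unpaired(
                resp[bp.categories == cat_a],
                resp[bp.categories == cat_b],
                n_perm,
                alternative=alternative,
                rng=_spawned_rng(seed, 3, counter),
            )
            rows.append(
                {
                    "site_set": set_name,
                    "cat_a": cat_a,
                    "cat_b": cat_b,
                    "observed": res.observed,
                    "p": res.p,
                }
            )
            counter += 1
    out = pd.DataFrame(rows)
    out["significant"] = fdr_bh(out["p"].to_numpy(), q)
    return out


def band_scan(
    epochs,
    bands: dict | None = None,
    *,
    seed: int = 0,
    **classify_kwargs,
) -> dict[str, SiteClassification]:
    """Run the site classification independently for each frequency
    band (voltage epochs in, one :class:`SiteClassification` per band
    out)."""
    from .preprocess import STANDARD_BANDS, band_power

    if bands is None:
        bands = STANDARD_BANDS
    out = {}
    for name, spec in bands.items():
        bp = band_power(epochs, spec)
        out[name] = classify_sites(bp, seed=seed, **classify_kwargs)
    return out
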