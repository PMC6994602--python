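"""Trial-level response onset latency (ROL) and spatial gradients.

Onset detection runs on the non-smoothed band power: each trial is
peak-normalized, averaged into 30 ms bins sliding in 2 ms steps, and the
onset is the start of the earliest run of 25 consecutive bins whose
means all exceed the baseline mean plus one baseline standard deviation
(both estimated on the trial-averaged baseline trace).  A site's ROL is
the median over detected trials, valid only when at least half the
trials yield an onset.  Gradients relate per-site ROL and selectivity
to the posterior-anterior (y) position by Spearman correlation, either
absolutely or relative to each subject's most face-selective site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import normalize_peak

__all__ = [
    "ROLParams",
    "ROLEstimate",
    "GradientResult",
    "rol_trial",
    "rol_site",
    "gradient_analysis",
    "match_sites",
]


@dataclass(frozen=True)
class ROLParams:
    """Onset-detection parameters (all times in ms).

    bin_width 30 with bin_step 2 gives 28 ms overlap; a response is an
    onset only if 25 consecutive bins exceed threshold, which rejects
    transient pathological spikes.  ``search_window`` bounds where a run
    may *start*; the run itself may complete later in the epoch.
    """

    bin_width_ms: float = 30.0
    bin_step_ms: float = 2.0
    n_consecutive: int = 25
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    threshold_sd: float = 1.0
    min_detection_fraction: float = 0.5
    search_window_ms: tuple[float, float] = (0.0, 500.0)
    peak_window_ms: tuple[float, float] = (0.0, 600.0)
    #: how the shared detection threshold is estimated from the
    #: (peak-normalized) baselines:
    #:  "trial-pooled"  - per-trial baseline mean and SD, averaged across
    #:                    trials (default: the SD reflects single-trial
    #:                    noise, which is what trial-level detection must
    #:                    exceed);
    #:  "average-trace" - mean and SD over time of the trial-averaged
    #:                    baseline trace (SD shrinks as trials are added,
    #:                    making the threshold permissive for large n);
    #:  "per-trial"     - each trial thresholded on its own baseline.
    baseline_estimator: str = "trial-pooled"

    def __post_init__(self) -> None:
        if min(self.bin_width_ms, self.bin_step_ms) <= 0:
            raise ValueError("bin width and step must be positive")
        if self.n_consecutive < 1:
            raise ValueError("n_consecutive must be >= 1")


@dataclass
class ROLEstimate:
    """Per-site onset latency summary."""

    trial_onsets_ms: np.ndarray  # NaN where undetected
    median_ms: float  # NaN if no trial detected
    detection_fraction: float
    valid: bool
    n_trials: int


def _bin_means(trace: np.ndarray, times: np.ndarray, params: ROLParams):
    """Means over sliding bins [t, t+width) starting at stimulus onset;
    returns (bin start times, bin means)."""
    t_end = times[-1] + (times[1] - times[0])
    starts = []
    t0 = 0.0
    while t0 + params.bin_width_ms <= t_end + 1e-9:
        starts.append(t0)
        t0 += params.bin_step_ms
    starts = np.array(starts)
    # cumulative-sum bin means on the uniform sample grid
    lo = np.searchsorted(times, starts - 1e-9, side="left")
    hi = np.searchsorted(times, starts + params.bin_width_ms - 1e-9, side="left")
    csum = np.concatenate([[0.0], np.cumsum(trace)])
    counts = np.maximum(hi - lo, 1)
    means = (csum[hi] - csum[lo]) / counts
    return starts, means


def rol_trial(
    trace: np.ndarray,
    times: np.ndarray,
    params: ROLParams = ROLParams(),
    *,
    threshold: float | None = None,
) -> float:
    """Onset latency of one trial, or NaN if undetected.

    ``threshold`` is normally the site-level baseline mean + 1 SD from
    :func:`rol_site`; when omitted it is computed from this trial's own
    baseline.  The trace must already be peak-normalized when a shared
    threshold is used.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if threshold is None:
        bmask = (times >= params.baseline_window_ms[0]) & (
            times < params.baseline_window_ms[1]
        )
        if not bmask.any():
            raise ValueError("trace does not cover the baseline window")
        threshold = trace[bmask].mean() + params.threshold_sd * trace[bmask].std()
    starts, means = _bin_means(trace, times, params)
    above = means > threshold
    k = params.n_consecutive
    if len(above) < k:
        return float("nan")
    # candidate i starts a qualifying run iff bins i..i+k-1 all exceed threshold
    ok = np.convolve(above.astype(int), np.ones(k, dtype=int), mode="valid") == k
    lo, hi = params.search_window_ms
    in_window = (starts[: len(ok)] >= lo) & (starts[: len(ok)] <= hi)
    hits = np.flatnonzero(ok & in_window)
    return float(starts[hits[0]]) if len(hits) else float("nan")


def rol_site(
    trials: np.ndarray,
    times: np.ndarray,
    params: ROLParams = ROLParams(),
) -> ROLEstimate:
    """Site-level ROL: peak-normalize trials, derive the shared
    threshold from the trial-averaged baseline, detect per-trial onsets
    and take their median.  Invalid (and so excluded downstream) when
    fewer than half the trials yield an onset."""
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    times = np.asarray(times, dtype=float)
    n = trials.shape[0]
    if n == 0:
        raise ValueError("need at least one trial")
    norm, valid_mask = normalize_peak(trials, times, peak_window_ms=params.peak_window_ms)
    bmask = (times >= params.baseline_window_ms[0]) & (times < params.baseline_window_ms[1])
    if not bmask.any():
        raise ValueError("trials do not cover the baseline window")
    onsets = np.full(n, np.nan)
    base = norm[valid_mask][:, bmask] if valid_mask.any() else norm[:, bmask]
    if params.baseline_estimator == "per-trial":
        thresholds = norm[:, bmask].mean(axis=1) + params.threshold_sd * norm[:, bmask].std(axis=1)
    elif params.baseline_estimator == "average-trace":
        avg_base = base.mean(axis=0)
        thr = avg_base.mean() + params.threshold_sd * avg_base.std()
        thresholds = np.full(n, thr)
    elif params.baseline_estimator == "trial-pooled":
        thr = base.mean() + params.threshold_sd * float(base.std(axis=1).mean())
        thresholds = np.full(n, thr)
    else:
        raise ValueError(
            "baseline_estimator must be 'trial-pooled', 'average-trace' or 'per-trial'"
        )
    for i in range(n):
        if not valid_mask[i]:
            continue
        onsets[i] = rol_trial(norm[i], times, params, threshold=thresholds[i])
    detected = ~np.isnan(onsets)
    frac = float(detected.mean())
    median = float(np.median(onsets[detected])) if detected.any() else float("nan")
    return ROLEstimate(
        trial_onsets_ms=onsets,
        median_ms=median,
        detection_fraction=frac,
        valid=frac >= params.min_detection_fraction,
        n_trials=n,
    )


@dataclass
class GradientResult:
    """Spearman correlations of ROL and selectivity with the y axis."""

    rho_rol_y: float
    p_rol_y: float
    rho_sel_y: float
    p_sel_y: float
    n: int
    variant: str  # "absolute" | "best-site-referenced"
    region_means: dict  # posterior / mid / anterior mean ROL


REGION_BOUNDS = {"posterior": (-np.inf, -45.0), "mid": (-45.0, -35.0), "anterior": (-35.0, np.inf)}


def gradient_analysis(
    sites: pd.DataFrame,
    *,
    reference: str = "none",
    min_sites: int = 5,
) -> GradientResult:
    """Correlate per-site ROL and selectivity with y position.

    ``sites`` needs columns rol_ms, selectivity, y, and (for the
    referenced variant) subject.  With ``reference='best-site'`` the ROL
    and y of each subject's most selective site are subtracted before
    correlating, removing subject-specific timing offsets.
    """
    df = sites.dropna(subset=["rol_ms", "y"]).copy()
    if len(df) < min_sites:
        raise ValueError(f"need at least {min_sites} valid sites, got {len(df)}")
    variant = "absolute"
    if reference == "best-site":
        if "subject" not in df.columns:
            raise ValueError("best-site referencing requires a 'subject' column")
        variant = "best-site-referenced"
        for subj, grp in df.groupby("subject"):
            best = grp["selectivity"].idxmax()
            df.loc[grp.index, "rol_ms"] -= df.loc[best, "rol_ms"]
            df.loc[grp.index, "y"] -= df.loc[best, "y"]
    elif reference != "none":
        raise ValueError("reference must be 'none' or 'best-site'")
    def _spearman(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return float("nan"), float("nan")
        return stats.spearmanr(a, b)

    rho1, p1 = _spearman(df["rol_ms"].to_numpy(), df["y"].to_numpy())
    rho2, p2 = _spearman(df["selectivity"].to_numpy(), df["y"].to_numpy())
    regions = {}
    y_abs = sites.dropna(subset=["rol_ms", "y"])
    for name, (lo, hi) in REGION_BOUNDS.items():
        m = (y_abs["y"] >= lo) & (y_abs["y"] < hi)
        regions[name] = float(y_abs.loc[m, "rol_ms"].mean()) if m.any() else float("nan")
    return GradientResult(
        rho_rol_y=float(rho1),
        p_rol_y=float(p1),
        rho_sel_y=float(rho2),
        p_sel_y=float(p2),
        n=len(df),
        variant=variant,
        region_means=regions,
    )


def match_sites(
    face_sites: pd.DataFrame,
    task_sites: pd.DataFrame,
    *,
    y_tolerance_mm: float = 2.0,
) -> tuple[pd.DataFrame, float]:
    """Match each face-selective site to the nearest task-active site in
    y (a task-active site may serve several face sites); pairs farther
    than the tolerance are discarded.  Returns the pair table and the
    paired Wilcoxon signed-rank p-value on the ROL differences (NaN if
    fewer than one pair; 1.0 when all differences are zero).

    Both tables need columns name, y, rol_ms.
    """
    for df, what in ((face_sites, "face"), (task_sites, "task-active")):
        if not {"name", "y", "rol_ms"}.issubset(df.columns):
            raise ValueError(f"{what} table needs columns name, y, rol_ms")
    pairs = []
    ty = task_sites["y"].to_numpy(float)
    for _, row in face_sites.iterrows():
        if len(ty) == 0:
            break
        d = np.abs(ty - float(row["y"]))
        j = int(np.argmin(d))
        if d[j] <= y_tolerance_mm:
            pairs.append(
                {
                    "face_site": row["name"],
                    "task_site": task_sites.iloc[j]["name"],
                    "face_y": float(row["y"]),
                    "task_y": float(ty[j]),
                    "face_rol_ms": float(row["rol_ms"]),
                    "task_rol_ms": float(task_sites.iloc[j]["rol_ms"]),
                }
            )
    table = pd.DataFrame(pairs)
    if table.empty:
        return table, float("nan")
    diffs = table["face_rol_ms"].to_numpy() - table["task_rol_ms"].to_numpy()
    if np.allclose(diffs, 0):
        return table, 1.0
    p = float(stats.wilcoxon(diffs).pvalue)
    return table, p
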