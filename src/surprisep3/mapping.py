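"""Single-trial surprise-to-EEG mapping and group inference.

Per subject, the epoch at each channel is averaged within ten 48 ms
windows (centers 50..500 ms, baseline -100..0 ms subtracted), giving a
trials x windows matrix per channel.  The surprise term is regressed
onto each window vector after z-scoring both sides, using an
outlier-robust fit (iteratively reweighted least squares with Tukey
bisquare weights, intercept included); the standardized slope is the
subject's beta for that channel x window cell.  Group inference tests
the betas against zero per cell (and paired between models), and a
single pooled Benjamini-Hochberg threshold at the family alpha controls
the false discovery rate across all included test sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

BISQUARE_C = 4.685
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 50
MIN_TRIALS = 8


@dataclass(frozen=True)
class WindowSpec:
    """Ten 48 ms analysis windows spanning the cue-target interval."""

    centers_ms: tuple[float, ...] = tuple(float(c) for c in range(50, 501, 50))
    half_width_ms: float = 24.0
    baseline_ms: tuple[float, float] = (-100.0, 0.0)

    @property
    def n_windows(self) -> int:
        return len(self.centers_ms)


@dataclass
class BetaMap:
    """Per-subject standardized regression weights, channels x windows."""

    subject_id: str
    model_id: str
    beta: np.ndarray
    channel_labels: tuple[str, ...]
    centers_ms: tuple[float, ...]
    n_trials_used: int


@dataclass
class GroupStatMap:
    contrast: str                       # model_vs_zero:<model> | model1_vs_model2
    t: np.ndarray                       # channels x windows
    p: np.ndarray
    mean_beta: np.ndarray
    channel_labels: tuple[str, ...]
    centers_ms: tuple[float, ...]
    adjusted_alpha: float = np.nan
    sig_mask: np.ndarray = field(default=None)

    def apply_alpha(self, adjusted_alpha: float) -> None:
        self.adjusted_alpha = float(adjusted_alpha)
        self.sig_mask = self.p <= adjusted_alpha


def window_average(epochs, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Baseline-corrected window means, shape (trials, channels, windows).

    Window endpoints are inclusive (25 samples per 48 ms window at
    500 Hz); the mean of the baseline samples is subtracted per trial
    and channel before averaging.
    """
    t = epochs.times_ms
    lo, hi = spec.baseline_ms
    if t[0] > lo or t[-1] < max(c + spec.half_width_ms for c in spec.centers_ms):
        raise ValueError("window specification exceeds epoch bounds")
    base = (t >= lo) & (t <= hi)
    data = epochs.data - epochs.data[:, :, base].mean(axis=2, keepdims=True)
    cols = []
    for c in spec.centers_ms:
        sel = (t >= c - spec.half_width_ms) & (t <= c + spec.half_width_ms)
        cols.append(data[:, :, sel].mean(axis=2))
    return np.stack(cols, axis=2)


def _zscore(x: np.ndarray, axis=0) -> np.ndarray:
    m = x.mean(axis=axis, keepdims=True)
    s = x.std(axis=axis, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (x - m) / s


def robust_slopes(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """IRLS bisquare slope of each column of `Y` on `x` (intercept included).

    Vectorized across response columns: shapes (n,) and (n, m) -> (m,).
    The residual scale is re-estimated each iteration as the median
    absolute residual / 0.6745.  Columns where the fit degenerates
    (zero residual scale) keep their current estimate.
    """
    n, m = Y.shape
    x = x.astype(float)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]          # (2, m) OLS start
    for _ in range(IRLS_MAX_ITER):
        resid = Y - X @ beta
        s = np.median(np.abs(resid), axis=0) / 0.6745
        s = np.where(s > 0, s, np.inf)                   # zero scale: weights all 1
        u = resid / (BISQUARE_C * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        # weighted normal equations, closed form for the 2-param design
        sw = w.sum(axis=0)
        swx = w.T @ x
        swxx = w.T @ (x * x)
        swy = (w * Y).sum(axis=0)
        swxy = (w * Y * x[:, None]).sum(axis=0)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) > 1e-12, det, np.nan)
        b0 = (swxx * swy - swx * swxy) / det
        b1 = (sw * swxy - swx * swy) / det
        new = np.vstack([b0, b1])
        bad = ~np.isfinite(new)
        new[bad] = beta[bad]
        if np.nanmax(np.abs(new - beta)) < IRLS_TOL:
            beta = new
            break
        beta = new
    return beta[1]


def fit_surprise_map(
    windowed: np.ndarray,
    series: pd.DataFrame,
    subject_id: str = "",
    channel_labels: tuple[str, ...] = (),
    centers_ms: tuple[float, ...] = tuple(float(c) for c in range(50, 501, 50)),
) -> BetaMap:
    """Regress a surprise series onto windowed single-trial EEG.

    `windowed` has shape (trials, channels, windows), rows aligned with
    the scored trials of `series`.  Predictor and response are z-scored
    across trials; cells with zero variance get NaN betas.
    """
    x = np.asarray(series["surprise"], dtype=float)
    n, n_ch, n_win = windowed.shape
    if len(x) != n:
        raise ValueError("surprise series and windowed trials are misaligned")
    if n < MIN_TRIALS:
        raise ValueError(f"need at least {MIN_TRIALS} trials, got {n}")
    model_id = str(series["model_id"].iloc[0]) if "model_id" in series else "unknown"

    Y = _zscore(windowed.reshape(n, n_ch * n_win))
    if x.std(ddof=1) == 0:
        log.warning("%s: zero-variance surprise predictor; betas absent", subject_id)
        beta = np.full((n_ch, n_win), np.nan)
    else:
        xz = _zscore(x)
        dead = ~np.isfinite(Y).all(axis=0)
        if dead.any():
            log.warning(
                "%s: %d zero-variance cells recorded as absent", subject_id, dead.sum()
            )
        Yf = np.where(np.isfinite(Y), Y, 0.0)
        beta = robust_slopes(xz, Yf)
        beta[dead] = np.nan
        beta = beta.reshape(n_ch, n_win)
    return BetaMap(
        subject_id=subject_id,
        model_id=model_id,
        beta=beta,
        channel_labels=tuple(channel_labels),
        centers_ms=tuple(centers_ms),
        n_trials_used=n,
    )


def bh_adjusted_alpha(pvals: np.ndarray, family_alpha: float) -> float:
    """Benjamini-Hochberg step-up threshold over a pooled p-value family.

    Returns the largest p(k) with p(k) <= k * alpha / m (0.0 when no
    p-value qualifies, so that no test is declared significant).
    """
    p = np.sort(np.asarray(pvals, dtype=float).ravel())
    p = p[np.isfinite(p)]
    m = p.size
    if m == 0:
        raise ValueError("no finite p-values supplied")
    crit = family_alpha * np.arange(1, m + 1) / m
    ok = np.nonzero(p <= crit)[0]
    return float(p[ok[-1]]) if ok.size else 0.0


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test alpha for `m` planned comparisons."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return family_alpha / m


def _cellwise_t(betas: np.ndarray, betas2: np.ndarray | None = None):
    """One-sample (or paired) t across the subject axis with NaN handling."""
    x = betas if betas2 is None else betas - betas2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_1samp(x, 0.0, axis=0, nan_policy="omit")
    return np.asarray(t, dtype=float), np.asarray(p, dtype=float)


def group_and_compare(
    beta_maps_m1: list[BetaMap],
    beta_maps_m2: list[BetaMap],
    family_alpha: float = 0.01,
) -> dict[str, GroupStatMap]:
    """Group-level inference over two models' beta maps.

    Per channel x window cell: one-sample t of each model's betas
    against zero, plus a paired t of model 1 vs model 2.  All three
    640-test sets are pooled into a single Benjamini-Hochberg correction
    at `family_alpha`, yielding one shared adjusted alpha.
    """
    if len(beta_maps_m1) < 3 or len(beta_maps_m2) < 3:
        raise ValueError("need at least 3 subjects per model")
    if len(beta_maps_m1) != len(beta_maps_m2):
        raise ValueError("paired model comparison needs matched subjects")
    b1 = np.stack([m.beta for m in beta_maps_m1])
    b2 = np.stack([m.beta for m in beta_maps_m2])
    labels = beta_maps_m1[0].channel_labels
    centers = beta_maps_m1[0].centers_ms

    maps = {}
    for name, arr, arr2 in (
        (f"model_vs_zero:{beta_maps_m1[0].model_id}", b1, None),
        (f"model_vs_zero:{beta_maps_m2[0].model_id}", b2, None),
        ("model1_vs_model2", b1, b2),
    ):
        t, p = _cellwise_t(arr, arr2)
        mean_beta = np.nanmean(arr if arr2 is None else arr - arr2, axis=0)
        maps[name] = GroupStatMap(
            contrast=name, t=t, p=p, mean_beta=mean_beta,
            channel_labels=labels, centers_ms=centers,
        )
    pooled = np.concatenate([m.p.ravel() for m in maps.values()])
    n_bad = np.sum(~np.isfinite(pooled))
    if n_bad:
        log.warning("%d cells excluded from FDR pooling (undefined p)", n_bad)
    alpha_adj = bh_adjusted_alpha(pooled[np.isfinite(pooled)], family_alpha)
    for m in maps.values():
        m.apply_alpha(alpha_adj)
    return maps


def group_vs_zero(
    beta_maps: list[BetaMap], family_alpha: float = 0.01
) -> GroupStatMap:
    """One-model group map with its own pooled BH threshold."""
    b = np.stack([m.beta for m in beta_maps])
    t, p = _cellwise_t(b)
    out = GroupStatMap(
        contrast=f"model_vs_zero:{beta_maps[0].model_id}",
        t=t, p=p, mean_beta=np.nanmean(b, axis=0),
        channel_labels=beta_maps[0].channel_labels,
        centers_ms=beta_maps[0].centers_ms,
    )
    out.apply_alpha(bh_adjusted_alpha(p[np.isfinite(p)], family_alpha))
    return out


def fit_rt_surprise(
    series: pd.DataFrame,
    rts: np.ndarray,
    blocks: np.ndarray | None = None,
    subset: str = "all",
) -> float:
    """Robust standardized slope of RT on the surprise term for one subject.

    `rts` aligns with the scored trials of `series` (NaN where no
    response was made).  ``subset='first_half'`` restricts to blocks 1-2.
    Returns NaN when fewer than 8 usable trials remain or a side has
    zero variance.
    """
    if subset not in ("all", "first_half"):
        raise ValueError("subset must be 'all' or 'first_half'")
    x = np.asarray(series["surprise"], dtype=float)
    y = np.asarray(rts, dtype=float)
    if len(x) != len(y):
        raise ValueError("surprise series and RTs are misaligned")
    keep = np.isfinite(y)
    if subset == "first_half":
        if blocks is None:
            raise ValueError("first_half subset requires block labels")
        keep &= np.isin(np.asarray(blocks), (1, 2))
    x, y = x[keep], y[keep]
    if len(x) < MIN_TRIALS:
        log.warning("subject skipped: only %d usable RT trials", len(x))
        return np.nan
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        log.warning("subject skipped: zero-variance RT or surprise")
        return np.nan
    return float(robust_slopes(_zscore(x), _zscore(y)[:, None])[0])


def group_rt_test(betas: np.ndarray) -> dict:
    """Group one-sample t over per-subject RT betas (NaN-skipping)."""
    b = np.asarray(betas, dtype=float)
    b = b[np.isfinite(b)]
    if b.size < 3:
        raise ValueError("need at least 3 subjects with usable RT fits")
    t, p = stats.ttest_1samp(b, 0.0)
    return {"t": float(t), "p": float(p), "mean_beta": float(b.mean()), "n": int(b.size)}
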