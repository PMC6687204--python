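"""Condition ERPs, P3/N1 peak extraction, and the cross-task
correlation / bootstrap-difference / partial-regression analyses.

The cross-task logic: if the fronto-central P3 after unexpected cues
(CMO task) and after stop-signals (SST) index the same process, their
subject-level peak amplitudes should correlate positively, and that
correlation should exceed control correlations between unrelated
waveform pairs.  Control N1 amplitudes are sign-inverted before
correlating so every pair shares a common directionality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .montage import channel_index

log = logging.getLogger(__name__)

P3_WINDOW_MS = (250.0, 500.0)
N1_WINDOW_MS = (100.0, 300.0)
P3_CHANNELS = ("FCz", "Cz")
N1_CHANNELS = ("Oz", "O1", "O2")


@dataclass
class PeakMeasure:
    subject_id: str
    task: str
    condition: str
    component: str                  # P3 | N1
    amplitude_uv: float
    latency_ms: float
    channels_used: tuple[str, ...]


def condition_erp(epochs, mask=None) -> np.ndarray:
    """Trial-average waveform per channel, baseline-corrected (-100..0 ms).

    `mask` optionally selects trials (boolean array over rows of
    ``epochs.events``); an empty selection is an error.
    """
    data = epochs.data if mask is None else epochs.data[np.asarray(mask)]
    if data.shape[0] == 0:
        raise ValueError("condition selects no trials")
    t = epochs.times_ms
    base = (t >= -100.0) & (t <= 0.0)
    data = data - data[:, :, base].mean(axis=2, keepdims=True)
    return data.mean(axis=0)


def peak_amplitude(
    erp: np.ndarray,
    times_ms: np.ndarray,
    channel_labels,
    component: str,
    channels: tuple[str, ...] | None = None,
    subject_id: str = "",
    task: str = "",
    condition: str = "",
) -> PeakMeasure:
    """Peak of the channel-averaged waveform within the component window.

    P3: largest positive deflection 250-500 ms at FCz/Cz; N1: largest
    negative deflection 100-300 ms at Oz/O1/O2.  The listed channels are
    averaged into one waveform before peak detection; ties break to the
    earliest sample.
    """
    if component == "P3":
        window, default_ch, sign = P3_WINDOW_MS, P3_CHANNELS, 1.0
    elif component == "N1":
        window, default_ch, sign = N1_WINDOW_MS, N1_CHANNELS, -1.0
    else:
        raise ValueError("component must be 'P3' or 'N1'")
    channels = tuple(channels or default_ch)
    idx = channel_index(channel_labels, channels)
    wave = erp[idx].mean(axis=0)
    sel = np.nonzero((times_ms >= window[0]) & (times_ms <= window[1]))[0]
    scored = sign * wave[sel]
    k = sel[int(np.argmax(scored))]     # argmax takes the earliest maximum
    return PeakMeasure(
        subject_id=subject_id, task=task, condition=condition, component=component,
        amplitude_uv=float(wave[k]), latency_ms=float(times_ms[k]),
        channels_used=channels,
    )


# ---------------------------------------------------------------------------
# subject panel and correlation analyses
# ---------------------------------------------------------------------------

#: measures whose raw sign is negative; inverted before correlating
N1_COLUMNS = ("sst_go_n1", "cmo_target_n1")


def _directional(panel: pd.DataFrame) -> pd.DataFrame:
    out = panel.copy()
    for col in N1_COLUMNS:
        if col in out:
            out[col] = -out[col]
    return out


def corr_panel(
    panel: pd.DataFrame,
    target_pairs: list[tuple[str, str]],
    control_pairs: list[tuple[str, str]],
    n_iter: int = 5000,
    seed: int = 0,
) -> dict:
    """Pearson correlations plus scrambled-assignment bootstrap tests.

    For every (target, control) combination the observed difference
    r_target - r_control is compared against a null distribution built
    by `n_iter` scrambles in which each measure's column is permuted
    independently across subjects (preserving marginals, destroying
    subject coupling); p = proportion of null differences >= observed
    (one-sided).
    """
    if n_iter < 1000:
        raise ValueError("n_iter must be at least 1000")
    cols = sorted({c for pair in target_pairs + control_pairs for c in pair})
    data = _directional(panel)[cols].dropna()
    n = len(data)
    if n < 10:
        raise ValueError(f"need at least 10 complete rows, got {n}")
    X = data.to_numpy(dtype=float)
    col_ix = {c: i for i, c in enumerate(cols)}
    sd = X.std(axis=0, ddof=1)
    for c in cols:
        if sd[col_ix[c]] == 0:
            log.warning("zero-variance measure %s: its pairs are skipped", c)

    def r_of(A: np.ndarray, a: str, b: str) -> float:
        i, j = col_ix[a], col_ix[b]
        if A[:, i].std(ddof=1) == 0 or A[:, j].std(ddof=1) == 0:
            return np.nan
        return float(np.corrcoef(A[:, i], A[:, j])[0, 1])

    result = {"n": n, "pairs": {}, "differences": {}}
    for a, b in target_pairs + control_pairs:
        r = r_of(X, a, b)
        if np.isnan(r):
            continue
        p = float(stats.pearsonr(X[:, col_ix[a]], X[:, col_ix[b]])[1])
        result["pairs"][f"{a}~{b}"] = {"r": r, "p": p}

    rng = np.random.default_rng(seed)
    # null distribution of every pair's r under independent scrambling
    null_r = {pair: np.empty(n_iter) for pair in target_pairs + control_pairs}
    Xs = X.copy()
    for it in range(n_iter):
        for j in range(X.shape[1]):
            Xs[:, j] = X[rng.permutation(n), j]
        for pair in null_r:
            null_r[pair][it] = r_of(Xs, *pair)

    for tp in target_pairs:
        rt = r_of(X, *tp)
        for cp in control_pairs:
            rc = r_of(X, *cp)
            if np.isnan(rt) or np.isnan(rc):
                continue
            obs = rt - rc
            null = null_r[tp] - null_r[cp]
            pboot = float(np.mean(null >= obs))
            result["differences"][f"({tp[0]}~{tp[1]})-({cp[0]}~{cp[1]})"] = {
                "observed_diff": obs,
                "p_boot": pboot,
            }
    return result


def partial_regression(
    panel: pd.DataFrame,
    criterion: str,
    predictor: str,
    nuisances: list[str],
) -> dict:
    """Multiple linear regression of `criterion` on `predictor` +
    `nuisances`; reports the predictor's partial coefficient test."""
    cols = [criterion, predictor, *nuisances]
    data = _directional(panel)[cols].dropna()
    if len(data) < len(cols) + 1:
        raise ValueError("too few complete rows for the requested model")
    X = sm.add_constant(data[[predictor, *nuisances]].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("exactly collinear predictors")
    fit = sm.OLS(data[criterion].to_numpy(dtype=float), X).fit()
    return {
        "t": float(fit.tvalues[1]),
        "p": float(fit.pvalues[1]),
        "coef": float(fit.params[1]),
        "n": int(len(data)),
    }
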