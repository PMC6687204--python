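"""Stop-signal behavior summaries, integration-method SSRT, and the
backward-stepping onset of the stop-signal P3.

Under the independent race model, the response on a stop trial escapes
inhibition iff the go process finishes before SSD + SSRT.  SSRT is
estimated with the integration method: go misses are replaced with the
slowest observed go RT, the go RT distribution is integrated up to the
observed response rate given a stop signal, and the mean SSD is
subtracted from that quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .montage import channel_index

ONSET_PEAK_WINDOW_MS = (200.0, 400.0)
ONSET_ALPHA = 0.05


@dataclass
class StopBehaviorSummary:
    subject_id: str
    go_rt_ms: float
    failed_stop_rt_ms: float
    ssrt_ms: float
    p_respond_given_stop: float
    mean_ssd_ms: float


@dataclass
class OnsetResult:
    subject_id: str
    condition: str                  # stop_success | stop_fail
    onset_ms: float | None
    peak_ms: float


def ssrt_integration(
    go_rts_ms, miss_flags, p_respond_given_stop: float, mean_ssd_ms: float
) -> float:
    """Integration-method SSRT (ms).

    Misses enter the go distribution at the maximum observed go RT; the
    SSRT is the go RT at rank ``ceil(p_respond * n)`` of the sorted
    distribution minus the mean SSD.
    """
    if not 0 < p_respond_given_stop <= 1:
        raise ValueError("p_respond_given_stop must lie in (0, 1]")
    rts = np.asarray(go_rts_ms, dtype=float)
    miss = np.asarray(miss_flags, dtype=bool)
    if rts.size < 20:
        raise ValueError("need at least 20 go trials")
    observed = rts[~miss]
    if observed.size == 0:
        raise ValueError("all go trials are misses")
    rts = np.where(miss, observed.max(), rts)
    rts.sort()
    rank = math.ceil(p_respond_given_stop * rts.size)
    return float(rts[rank - 1] - mean_ssd_ms)


def summarize_stop_behavior(trials, subject_id: str = "") -> StopBehaviorSummary:
    """Behavioral summary + SSRT from a list of stop-task trials."""
    go = [t for t in trials if not t.is_stop]
    stop = [t for t in trials if t.is_stop]
    if not go or not stop:
        raise ValueError("need both go and stop trials")
    go_rts = np.array(
        [t.rt_ms if t.rt_ms is not None else np.nan for t in go], dtype=float
    )
    miss = np.isnan(go_rts)
    go_rts = np.where(miss, 0.0, go_rts)
    failed = [t.rt_ms for t in stop if t.outcome == "stop_fail"]
    p_resp = np.mean([t.outcome == "stop_fail" for t in stop])
    mean_ssd = float(np.mean([t.ssd_ms for t in stop]))
    return StopBehaviorSummary(
        subject_id=subject_id,
        go_rt_ms=float(np.mean(go_rts[~miss])) if (~miss).any() else np.nan,
        failed_stop_rt_ms=float(np.mean(failed)) if failed else np.nan,
        ssrt_ms=ssrt_integration(go_rts, miss, float(p_resp), mean_ssd)
        if p_resp > 0
        else np.nan,
        p_respond_given_stop=float(p_resp),
        mean_ssd_ms=mean_ssd,
    )


def _samplewise_p(stop_amp: np.ndarray, go_amp: np.ndarray, k: int) -> float:
    """Two-sample t p-value at sample k; degenerate (zero-variance)
    samples count as significant iff the means differ."""
    a, b = stop_amp[:, k], go_amp[:, k]
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 0.0 if a.mean() != b.mean() else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(p) if np.isfinite(p) else 1.0

def p3_onset(
    stop_epochs,
    go_epochs,
    subject_id: str = "",
    condition: str = "stop_success",
    channels: tuple[str, ...] = ("FCz", "Cz"),
    stop_mask=None,
) -> OnsetResult:
    """Backward-stepping onset of the stop-signal P3 difference wave.

    The stop-minus-go difference of the fronto-central (FCz/Cz-average)
    waveform is maximal somewhere in 200-400 ms after the stop signal;
    stepping backwards sample-by-sample from that peak, the onset is the
    last sample at which a two-sample t between stop- and go-trial
    single-trial amplitudes is still significant at p < .05.  If the
    peak itself is not significant the onset is undefined.
    """
    si = channel_index(stop_epochs.channel_labels, channels)
    gi = channel_index(go_epochs.channel_labels, channels)
    t_ms = stop_epochs.times_ms
    stop_amp = stop_epochs.data[:, si, :].mean(axis=1)
    if stop_mask is not None:
        stop_amp = stop_amp[np.asarray(stop_mask)]
    go_amp = go_epochs.data[:, gi, :].mean(axis=1)
    if stop_amp.shape[0] < 10 or go_amp.shape[0] < 10:
        raise ValueError("need at least 10 trials per condition")
    # baseline-correct both sets over -100..0 ms
    base = (t_ms >= -100.0) & (t_ms <= 0.0)
    stop_amp = stop_amp - stop_amp[:, base].mean(axis=1, keepdims=True)
    go_amp = go_amp - go_amp[:, base].mean(axis=1, keepdims=True)

    diff = stop_amp.mean(axis=0) - go_amp.mean(axis=0)
    sel = np.nonzero((t_ms >= ONSET_PEAK_WINDOW_MS[0]) & (t_ms <= ONSET_PEAK_WINDOW_MS[1]))[0]
    k_peak = sel[int(np.argmax(diff[sel]))]
    peak_ms = float(t_ms[k_peak])

    if _samplewise_p(stop_amp, go_amp, k_peak) >= ONSET_ALPHA:
        return OnsetResult(subject_id, condition, None, peak_ms)
    k = k_peak
    while k > 0 and _samplewise_p(stop_amp, go_amp, k - 1) < ONSET_ALPHA:
        k -= 1
    return OnsetResult(subject_id, condition, float(t_ms[k]), peak_ms)


def validate_stop_component(onsets: list[dict], ssrt_ms: np.ndarray) -> dict:
    """Two validation statistics for the selected stop-P3 signal.

    `onsets` holds per-subject dicts with keys ``stop_success`` and
    ``stop_fail`` (onset in ms or None).  Reports the paired t of
    success vs fail onsets and the Pearson correlation between
    success-trial onset and SSRT; subjects with undefined onsets are
    excluded pairwise.
    """
    succ = np.array(
        [d.get("stop_success") if d.get("stop_success") is not None else np.nan for d in onsets],
        dtype=float,
    )
    fail = np.array(
        [d.get("stop_fail") if d.get("stop_fail") is not None else np.nan for d in onsets],
        dtype=float,
    )
    ssrt = np.asarray(ssrt_ms, dtype=float)
    if np.sum(np.isfinite(succ)) < 10:
        raise ValueError("need at least 10 subjects with defined onsets")

    pair = np.isfinite(succ) & np.isfinite(fail)
    if pair.sum() < 3:
        raise ValueError("fewer than 3 subjects usable for the paired test")
    d = succ[pair] - fail[pair]
    if np.allclose(d, 0):
        t_pair, p_pair = 0.0, 1.0
    else:
        t_pair, p_pair = stats.ttest_rel(succ[pair], fail[pair])
    cor = np.isfinite(succ) & np.isfinite(ssrt)
    if cor.sum() < 3:
        raise ValueError("fewer than 3 subjects usable for the correlation")
    if succ[cor].std() == 0 or ssrt[cor].std() == 0:
        r, p_r = np.nan, np.nan          # correlation undefined for constants
    else:
        r, p_r = stats.pearsonr(succ[cor], ssrt[cor])
    return {
        "paired_t": float(t_pair),
        "paired_p": float(p_pair),
        "n_paired": int(pair.sum()),
        "onset_ssrt_r": float(r),
        "onset_ssrt_p": float(p_r),
        "n_corr": int(cor.sum()),
    }
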