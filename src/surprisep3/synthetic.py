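"""Synthetic cohorts for the cross-modal oddball (CMO) and stop-signal (SST)
tasks with known ground truth.

The generator emulates the study design end-to-end so that every
downstream stage is testable without recorded data:

* CMO cue sequences — 4 blocks x 60 trials, 80/10/10 per cent
  standard / unexpected-auditory / unexpected-visual, with the ordering
  constraints of the design (first three trials of each block standard,
  no two consecutive unexpected cues, equal per-block counts of the two
  unexpected modalities).
* SST behavior — an independent horse-race between an ex-Gaussian go
  process and a normally distributed stop process (SSRT), with the
  per-direction 50 ms stop-signal-delay staircases starting at 200 ms.
* 64-channel, 500 Hz epochs (-100..700 ms) containing a fronto-central
  P3 source whose single-trial amplitude is a linear function of a
  chosen generative surprise term, an occipital N1 source to visual
  arrow stimuli, distractor sources, a known mixing matrix, and
  spatially correlated sensor noise.  Subject-level stop-P3 and
  surprise-P3 gains share a configurable correlation, inducing the
  cross-task amplitude coupling under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import surprise as surprise_mod
from .montage import CHANNELS_64, FRONTOCENTRAL, OCCIPITAL, channel_index, sensor_layout

CUE_TYPES = ("standard", "unexpected_auditory", "unexpected_visual")
SFREQ_HZ = 500.0
EPOCH_TMIN_MS = -100.0
EPOCH_TMAX_MS = 700.0
#: cue-to-target interval in the oddball task (ms)
CUE_TARGET_SOA_MS = 500.0


# ---------------------------------------------------------------------------
# trial records
# ---------------------------------------------------------------------------

@dataclass
class OddballTrial:
    index: int                      # 1-based position in session
    block: int                      # 1..n_blocks
    cue_type: str                   # one of CUE_TYPES
    target_direction: str           # left | right
    iti_jitter_ms: int              # 100..500 in 100 ms steps
    rt_ms: float | None = None
    response: str = "none"          # left | right | none
    correct: bool = False


@dataclass
class StopTrial:
    index: int
    go_direction: str               # left | right
    is_stop: bool
    ssd_ms: float | None = None     # present iff is_stop
    outcome: str = "go_correct"     # go_correct|go_error|go_miss|stop_success|stop_fail
    rt_ms: float | None = None


@dataclass
class RaceParams:
    """Independent-race parameters: ex-Gaussian go finish times and a
    normally distributed stop-signal reaction time (ms)."""

    go_mu: float = 400.0
    go_sigma: float = 50.0
    go_tau: float = 100.0
    ssrt_mean: float = 250.0
    ssrt_sd: float = 30.0
    p_miss: float = 0.026
    p_error: float = 0.01

    def validate(self) -> None:
        for name in ("go_mu", "go_sigma", "go_tau", "ssrt_mean", "ssrt_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"race parameter {name} must be non-negative")
        if self.go_mu <= 0 or self.ssrt_mean <= 0:
            raise ValueError("go_mu and ssrt_mean must be positive")


def trials_to_frame(trials: Sequence) -> pd.DataFrame:
    """Tabulate a list of trial dataclasses."""
    return pd.DataFrame([vars(t) for t in trials])


# ---------------------------------------------------------------------------
# oddball sequence
# ---------------------------------------------------------------------------

def gen_oddball_sequence(
    n_blocks: int = 4,
    trials_per_block: int = 60,
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    behavior: "OddballBehavior | None" = None,
) -> list[OddballTrial]:
    """Generate a pseudorandom cross-modal oddball cue sequence.

    Constraints enforced per block: the first three trials carry standard
    cues, no two consecutive trials carry unexpected cues, and the two
    unexpected modalities occur equally often.  Defaults give 240 trials
    split 192/24/24.

    `behavior`, when given (default: realistic behavior), fills in
    reaction times, responses and correctness; pass
    ``behavior=OddballBehavior(enabled=False)`` for a pure sequence.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    p_std, p_aud, p_vis = proportions
    n_aud = p_aud * trials_per_block
    n_vis = p_vis * trials_per_block
    if abs(n_aud - round(n_aud)) > 1e-9 or abs(n_vis - round(n_vis)) > 1e-9:
        raise ValueError("proportions must yield integer per-block counts")
    n_aud, n_vis = int(round(n_aud)), int(round(n_vis))
    if n_aud != n_vis and min(n_aud, n_vis) > 0:
        # equal-count constraint only binds when both modalities occur
        raise ValueError("per-block unexpected counts must be equal across modalities")
    n_unexp = n_aud + n_vis
    n_free = trials_per_block - 3          # positions 4..end may be unexpected
    # non-adjacent placement of n_unexp among n_free slots needs
    # n_free - (n_unexp - 1) >= n_unexp
    if n_unexp > 0 and n_free - n_unexp + 1 < n_unexp:
        raise ValueError(
            "infeasible constraints: too many unexpected trials to avoid adjacency"
        )

    trials: list[OddballTrial] = []
    idx = 1
    for block in range(1, n_blocks + 1):
        cues = np.array(["standard"] * trials_per_block, dtype=object)
        if n_unexp:
            # sample a non-adjacent position subset uniformly via the
            # gap construction: choose from the compressed range, then
            # re-expand so consecutive picks are >= 2 apart
            base = rng.choice(n_free - n_unexp + 1, size=n_unexp, replace=False)
            base.sort()
            positions = 3 + base + np.arange(n_unexp)       # 0-based, >= 3
            labels = np.array(
                ["unexpected_auditory"] * n_aud + ["unexpected_visual"] * n_vis,
                dtype=object,
            )
            rng.shuffle(labels)
            cues[positions] = labels
        for cue in cues:
            trials.append(
                OddballTrial(
                    index=idx,
                    block=block,
                    cue_type=str(cue),
                    target_direction=("left", "right")[rng.integers(2)],
                    iti_jitter_ms=int(rng.integers(1, 6) * 100),
                )
            )
            idx += 1

    behavior = behavior if behavior is not None else OddballBehavior()
    if behavior.enabled:
        _fill_oddball_behavior(trials, behavior, rng)
    return trials


@dataclass
class OddballBehavior:
    """Reaction-time model for target responses in the oddball task.

    RT = ex-Gaussian base + a surprise-linked slowing (separate-term
    surprise) applied while the effect is still present (first half of
    the session), emulating the wear-off of cue-induced slowing."""

    enabled: bool = True
    mu: float = 450.0
    sigma: float = 50.0
    tau: float = 80.0
    surprise_slope_ms: float = 40.0
    slowing_blocks: tuple[int, ...] = (1, 2)
    p_miss: float = 0.02
    p_error: float = 0.01
    rt_limit_ms: float = 1000.0


def _fill_oddball_behavior(trials, b: OddballBehavior, rng) -> None:
    series = surprise_mod.compute_surprise(trials, model="separate")
    s_by_index = dict(zip(series["trial_index"], series["surprise"]))
    for t in trials:
        if rng.random() < b.p_miss:
            t.rt_ms, t.response, t.correct = None, "none", False
            continue
        rt = rng.normal(b.mu, b.sigma) + rng.exponential(b.tau)
        if t.block in b.slowing_blocks:
            rt += b.surprise_slope_ms * s_by_index.get(t.index, 0.0)
        rt = float(np.clip(rt, 150.0, b.rt_limit_ms))
        if rng.random() < b.p_error:
            t.response = "left" if t.target_direction == "right" else "right"
            t.correct = False
        else:
            t.response = t.target_direction
            t.correct = True
        t.rt_ms = rt


# ---------------------------------------------------------------------------
# stop-signal behavior
# ---------------------------------------------------------------------------

def gen_sst_behavior(
    n_trials: int = 300,
    p_stop: float = 1 / 3,
    race: RaceParams | None = None,
    seed: int = 0,
    ssd_start_ms: float = 200.0,
    ssd_step_ms: float = 50.0,
    ssrt_shift_ms: float = 0.0,
) -> list[StopTrial]:
    """Simulate stop-signal behavior under an independent race.

    Stop-signal delays are staircased independently per go direction:
    start at `ssd_start_ms`, +step after a successful stop, -step after
    a failed stop (floor 0).  The stop-trial proportion is `p_stop`
    exactly by construction.  A response is emitted on a stop trial iff
    the go finish time is below SSD + that trial's SSRT.

    `ssrt_shift_ms` offsets the subject's mean SSRT (used to couple
    stopping speed with the neural P3 onset in cohort simulations).
    """
    if not 0 < p_stop < 1:
        raise ValueError("p_stop must lie in (0, 1)")
    race = race or RaceParams()
    race.validate()
    rng = np.random.default_rng(seed)

    n_stop = int(round(n_trials * p_stop))
    is_stop = np.zeros(n_trials, dtype=bool)
    is_stop[rng.choice(n_trials, size=n_stop, replace=False)] = True

    ssd = {"left": ssd_start_ms, "right": ssd_start_ms}
    trials: list[StopTrial] = []
    for i in range(n_trials):
        direction = ("left", "right")[rng.integers(2)]
        go_rt = rng.normal(race.go_mu, race.go_sigma) + rng.exponential(race.go_tau)
        go_rt = max(go_rt, 100.0)
        miss = rng.random() < race.p_miss
        t = StopTrial(index=i + 1, go_direction=direction, is_stop=bool(is_stop[i]))
        if t.is_stop:
            t.ssd_ms = ssd[direction]
            ssrt = max(rng.normal(race.ssrt_mean + ssrt_shift_ms, race.ssrt_sd), 50.0)
            responded = (not miss) and go_rt < t.ssd_ms + ssrt
            if responded:
                t.outcome, t.rt_ms = "stop_fail", float(go_rt)
                ssd[direction] = max(ssd[direction] - ssd_step_ms, 0.0)
            else:
                t.outcome, t.rt_ms = "stop_success", None
                ssd[direction] = ssd[direction] + ssd_step_ms
        else:
            if miss:
                t.outcome, t.rt_ms = "go_miss", None
            elif rng.random() < race.p_error:
                t.outcome, t.rt_ms = "go_error", float(go_rt)
            else:
                t.outcome, t.rt_ms = "go_correct", float(go_rt)
        trials.append(t)
    return trials


def stop_success_rate(trials: Sequence[StopTrial]) -> float:
    """Proportion of stop trials on which the response was withheld."""
    stops = [t for t in trials if t.is_stop]
    if not stops:
        raise ValueError("no stop trials present")
    return sum(t.outcome == "stop_success" for t in stops) / len(stops)


# ---------------------------------------------------------------------------
# ground truth and epochs
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Generative parameters of a synthetic cohort.

    Regeneration from the same seed is bit-identical.  The mixing matrix
    is square (channels x channels): the first `n_sources` columns are
    the true source topographies (P3, N1, distractors) and the remainder
    are spatially smooth filler topographies, so the full decomposition
    spans channel space exactly.
    """

    n_subjects: int
    generative_model: Literal["separate", "common", "null"] = "separate"
    seed: int = 0
    # neural effect sizes (microvolts)
    b0_p3_uv: float = 5.0
    b1_p3_per_surprise: float = 8.0
    aud_vis_gain_ratio: float = 1.4
    stop_p3_uv: float = 5.0
    std_p3_uv: float = 5.0
    n1_uv: float = 5.0
    amp_noise_uv: float = 2.0
    distractor_uv: float = 2.0
    noise_sd_uv: float = 5.0
    # subject-level structure
    shared_gain_rho: float = 0.5
    gain_sd: float = 0.3
    onset_jitter_sd_ms: float = 20.0
    success_fail_onset_diff_ms: float = 30.0
    # kernels (ms)
    p3_on_ms: float = 250.0
    p3_peak_ms: float = 325.0
    p3_off_ms: float = 450.0
    stop_p3_on_ms: float = 200.0
    stop_p3_peak_ms: float = 300.0
    stop_p3_off_ms: float = 400.0
    n1_on_ms: float = 120.0
    n1_peak_ms: float = 170.0
    n1_off_ms: float = 220.0
    # montage / sources
    channel_labels: tuple[str, ...] = CHANNELS_64
    n_sources: int = 6
    p3_component: int = 0
    n1_component: int = 1
    # filled by make_ground_truth
    layout: np.ndarray = field(default=None, repr=False)
    mixing: np.ndarray = field(default=None, repr=False)
    stop_p3_gain: np.ndarray = field(default=None, repr=False)
    surprise_p3_gain: np.ndarray = field(default=None, repr=False)
    std_p3_gain: np.ndarray = field(default=None, repr=False)
    n1_gain: np.ndarray = field(default=None, repr=False)
    p3_onset_jitter_ms: np.ndarray = field(default=None, repr=False)

    def to_json_dict(self) -> dict:
        d = {}
        for k, v in vars(self).items():
            d[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return d


def _bump(t: np.ndarray, on: float, peak: float, off: float) -> np.ndarray:
    """Asymmetric raised-cosine bump: 0 outside [on, off], 1 at `peak`."""
    out = np.zeros_like(t, dtype=float)
    rise = (t >= on) & (t <= peak)
    fall = (t > peak) & (t <= off)
    if peak > on:
        out[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - on) / (peak - on)))
    if off > peak:
        out[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - peak) / (off - peak)))
    return out


def _gauss_topo(layout: np.ndarray, center: np.ndarray, width_m: float) -> np.ndarray:
    d2 = ((layout - center[None, :]) ** 2).sum(axis=1)
    topo = np.exp(-d2 / (2 * width_m**2))
    return topo / topo.max()


def _smoothing_operator(layout: np.ndarray, width_m: float = 0.04) -> np.ndarray:
    d2 = ((layout[:, None, :] - layout[None, :, :]) ** 2).sum(axis=-1)
    w = np.exp(-d2 / (2 * width_m**2))
    # unit output variance per channel for white unit-variance input
    return w / np.sqrt((w**2).sum(axis=1, keepdims=True))


def make_ground_truth(
    n_subjects: int,
    generative_model: str = "separate",
    seed: int = 0,
    **overrides,
) -> GroundTruth:
    """Draw a cohort-level ground truth: mixing matrix, subject gains,
    and P3-onset latency jitter (shared with SSRT in cohort simulation)."""
    truth = GroundTruth(
        n_subjects=n_subjects, generative_model=generative_model, seed=seed, **overrides
    )
    rng = np.random.default_rng([seed, 17])
    layout = sensor_layout(truth.channel_labels)
    n_ch = len(truth.channel_labels)
    fc = channel_index(truth.channel_labels, FRONTOCENTRAL)
    occ = channel_index(truth.channel_labels, OCCIPITAL)

    cols = np.empty((n_ch, n_ch))
    cols[:, truth.p3_component] = _gauss_topo(layout, layout[fc].mean(axis=0), 0.05)
    cols[:, truth.n1_component] = _gauss_topo(layout, layout[occ].mean(axis=0), 0.045)
    smooth = _smoothing_operator(layout)
    # distractor sources: smooth random topographies away from the two
    # structured sources
    for j in range(truth.n_sources):
        if j in (truth.p3_component, truth.n1_component):
            continue
        c = smooth @ rng.standard_normal(n_ch)
        cols[:, j] = c / np.abs(c).max()
    # filler columns so the decomposition is square and invertible
    for j in range(truth.n_sources, n_ch):
        c = 0.8 * (smooth @ rng.standard_normal(n_ch)) + 0.4 * rng.standard_normal(n_ch)
        cols[:, j] = c / np.abs(c).max()

    # subject gains: positive, lightly dispersed; stop and surprise gains
    # share correlation shared_gain_rho
    rho = float(np.clip(truth.shared_gain_rho, -1.0, 1.0))
    cov = np.array([[1.0, rho], [rho, 1.0]]) * truth.gain_sd**2
    g = rng.multivariate_normal([1.0, 1.0], cov, size=n_subjects)
    g = np.clip(g, 0.2, None)

    truth.layout = layout
    truth.mixing = cols
    truth.stop_p3_gain = g[:, 0]
    truth.surprise_p3_gain = g[:, 1]
    truth.n1_gain = np.clip(rng.normal(1.0, truth.gain_sd, size=n_subjects), 0.2, None)
    truth.p3_onset_jitter_ms = rng.normal(0.0, truth.onset_jitter_sd_ms, size=n_subjects)
    # standard cues evoke the baseline fronto-central response with a
    # subject gain independent of the stop/surprise gains
    truth.std_p3_gain = np.clip(rng.normal(1.0, truth.gain_sd, size=n_subjects), 0.2, None)
    return truth


@dataclass
class EpochSet:
    """Trials x channels x samples EEG (microvolts) with montage metadata."""

    subject_id: str
    data: np.ndarray
    channel_labels: tuple[str, ...]
    sensor_layout: np.ndarray
    sfreq_hz: float
    tmin_ms: float
    events: pd.DataFrame

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.tmin_ms + 1000.0 * np.arange(n) / self.sfreq_hz

    def select_trials(self, mask) -> "EpochSet":
        """Subset trials by boolean mask or integer positions."""
        mask = np.asarray(mask)
        events = self.events[mask] if mask.dtype == bool else self.events.iloc[mask]
        return replace(self, data=self.data[mask], events=events.reset_index(drop=True))

    def __post_init__(self):
        if self.data.shape[0] != len(self.events):
            raise ValueError("trial count of data and events disagree")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel count of data and labels disagree")


def _n_samples(tmin_ms: float, tmax_ms: float, sfreq: float) -> int:
    return int(round((tmax_ms - tmin_ms) / 1000.0 * sfreq)) + 1


def _render_epochs(
    rng: np.random.Generator,
    truth: GroundTruth,
    events: pd.DataFrame,
    sources_per_trial: list[list[tuple[int, float, float, float, float]]],
    subject_id: str,
    noise_sd: float | None = None,
    channel_idx: np.ndarray | None = None,
) -> EpochSet:
    """Assemble epochs from per-trial source events.

    Each source event is (component, amplitude_uv, on_ms, peak_ms, off_ms)
    on the epoch clock.  channel data = mixing[:, sources] @ activations
    + distractor activity + spatially correlated Gaussian noise.
    `channel_idx` restricts the rendered montage (the spatial noise is
    still driven by the full-montage white-noise field).
    """
    from scipy.signal import fftconvolve

    n_trials = len(events)
    n_ch_full = len(truth.channel_labels)
    n_samp = _n_samples(EPOCH_TMIN_MS, EPOCH_TMAX_MS, SFREQ_HZ)
    t = EPOCH_TMIN_MS + 1000.0 * np.arange(n_samp) / SFREQ_HZ
    noise_sd = truth.noise_sd_uv if noise_sd is None else noise_sd

    distractors = [
        j
        for j in range(truth.n_sources)
        if j not in (truth.p3_component, truth.n1_component)
    ]

    S = np.zeros((n_trials, truth.n_sources, n_samp))
    for i, evs in enumerate(sources_per_trial):
        for comp, amp, on, peak, off in evs:
            S[i, comp] += amp * _bump(t, on, peak, off)
    if distractors and truth.distractor_uv > 0:
        # smooth ongoing source activity: white noise through a ~100 ms
        # unit-energy Hann kernel
        hann = np.hanning(51)
        hann /= np.linalg.norm(hann)
        white = rng.standard_normal((n_trials, len(distractors), n_samp + 50))
        S[:, distractors, :] += truth.distractor_uv * fftconvolve(
            white, hann[None, None, :], mode="valid", axes=2
        )

    mix = truth.mixing[:, : truth.n_sources]
    smooth = _smoothing_operator(truth.layout)
    labels, layout = truth.channel_labels, truth.layout
    if channel_idx is not None:
        mix = mix[channel_idx]
        smooth = smooth[channel_idx]
        labels = tuple(np.asarray(truth.channel_labels)[channel_idx])
        layout = truth.layout[channel_idx]
    n_ch = mix.shape[0]

    flat = S.transpose(1, 0, 2).reshape(truth.n_sources, n_trials * n_samp)
    data = (mix @ flat).reshape(n_ch, n_trials, n_samp).transpose(1, 0, 2).copy()
    if noise_sd > 0:
        if channel_idx is None:
            colored = smooth @ rng.standard_normal((n_ch_full, n_trials * n_samp))
        else:
            # sample the restricted noise field directly from its exact
            # covariance (Cholesky factor of the smoothing operator's
            # subset Gram matrix) instead of mixing the full montage
            cov = smooth @ smooth.T
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(n_ch))
            colored = L @ rng.standard_normal((n_ch, n_trials * n_samp))
        data += colored.reshape(n_ch, n_trials, n_samp).transpose(1, 0, 2) * noise_sd

    return EpochSet(
        subject_id=subject_id,
        data=data,
        channel_labels=labels,
        sensor_layout=layout,
        sfreq_hz=SFREQ_HZ,
        tmin_ms=EPOCH_TMIN_MS,
        events=events.reset_index(drop=True),
    )


def gen_subject_epochs(
    truth: GroundTruth,
    subject: int,
    cmo_trials: Sequence[OddballTrial],
    sst_trials: Sequence[StopTrial],
    cmo_subset: str = "all",
    include_target_lock: bool = True,
    include_sst: bool = True,
    channels: Sequence[str] | None = None,
) -> dict[str, EpochSet]:
    """Generate all epoch sets for one subject.

    Returns a dict with keys:

    * ``cmo`` — cue-locked oddball epochs (all trials, or only
      unexpected-cue trials when ``cmo_subset='unexpected'``),
    * ``cmo_target`` — target-locked oddball epochs (arrow N1), present
      when `include_target_lock`,
    * ``sst_go`` — go-locked epochs of go trials,
    * ``sst_stop`` — stop-locked epochs of stop trials.

    `channels` optionally restricts the rendered montage (e.g. to the
    fronto-central and occipital measurement sites), which speeds up
    cohorts used only for peak-amplitude panels.
    """
    if subject < 0 or subject >= truth.n_subjects:
        raise IndexError("subject index out of range for ground truth")
    missing = [ch for ch in ("FCz", "Cz", "Oz") if ch not in truth.channel_labels]
    if missing:
        raise KeyError(f"montage lacks required channels: {missing}")
    ch_idx = None if channels is None else channel_index(truth.channel_labels, channels)
    sid = f"sub-{subject + 1:02d}"
    g_sur = truth.surprise_p3_gain[subject]
    g_stop = truth.stop_p3_gain[subject]
    g_std = truth.std_p3_gain[subject]
    g_n1 = truth.n1_gain[subject]
    jit = truth.p3_onset_jitter_ms[subject]

    # generative surprise term driving single-trial P3 amplitude
    if truth.generative_model == "null":
        s_by_index: dict[int, float] = {}
    else:
        ser = surprise_mod.compute_surprise(cmo_trials, model=truth.generative_model)
        s_by_index = dict(zip(ser["trial_index"], ser["surprise"]))

    out: dict[str, EpochSet] = {}

    # --- CMO, cue-locked -------------------------------------------------
    trials = list(cmo_trials)
    if cmo_subset == "unexpected":
        trials = [tr for tr in trials if tr.cue_type != "standard"]
    elif cmo_subset != "all":
        raise ValueError("cmo_subset must be 'all' or 'unexpected'")
    rng = np.random.default_rng([truth.seed, subject, 1])
    sources = []
    amps_true = []
    for tr in trials:
        ev = []
        if tr.cue_type != "standard":
            mod_gain = (
                truth.aud_vis_gain_ratio if tr.cue_type == "unexpected_auditory" else 1.0
            )
            amp = g_sur * mod_gain * (
                truth.b0_p3_uv
                + truth.b1_p3_per_surprise * s_by_index.get(tr.index, 0.0)
            ) + rng.normal(0.0, truth.amp_noise_uv)
        else:
            # standard cues evoke the baseline response without the
            # surprise-scaled addition (independent subject gain)
            amp = g_std * truth.std_p3_uv + rng.normal(0.0, truth.amp_noise_uv)
        ev.append(
            (truth.p3_component, amp, truth.p3_on_ms, truth.p3_peak_ms, truth.p3_off_ms)
        )
        # visual target arrow 500 ms after cue drives the occipital N1
        n1_amp = -(g_n1 * truth.n1_uv + rng.normal(0.0, truth.amp_noise_uv))
        ev.append(
            (
                truth.n1_component,
                n1_amp,
                CUE_TARGET_SOA_MS + truth.n1_on_ms,
                CUE_TARGET_SOA_MS + truth.n1_peak_ms,
                CUE_TARGET_SOA_MS + truth.n1_off_ms,
            )
        )
        sources.append(ev)
        amps_true.append(amp)
    events = trials_to_frame(trials)
    events["true_p3_amp_uv"] = amps_true
    out["cmo"] = _render_epochs(rng, truth, events, sources, sid, channel_idx=ch_idx)

    # --- CMO, target-locked ----------------------------------------------
    if include_target_lock:
        rng = np.random.default_rng([truth.seed, subject, 2])
        all_trials = list(cmo_trials)
        sources = []
        for tr in all_trials:
            ev = [
                (
                    truth.n1_component,
                    -(g_n1 * truth.n1_uv + rng.normal(0.0, truth.amp_noise_uv)),
                    truth.n1_on_ms,
                    truth.n1_peak_ms,
                    truth.n1_off_ms,
                )
            ]
            # tail of the cue-evoked P3 sits before/around target onset
            if tr.cue_type != "standard":
                amp = g_sur * (
                    truth.b0_p3_uv
                    + truth.b1_p3_per_surprise * s_by_index.get(tr.index, 0.0)
                )
            else:
                amp = g_std * truth.std_p3_uv
            ev.append(
                (
                    truth.p3_component,
                    amp,
                    truth.p3_on_ms - CUE_TARGET_SOA_MS,
                    truth.p3_peak_ms - CUE_TARGET_SOA_MS,
                    truth.p3_off_ms - CUE_TARGET_SOA_MS,
                )
            )
            sources.append(ev)
        out["cmo_target"] = _render_epochs(
            rng, truth, trials_to_frame(all_trials), sources, sid, channel_idx=ch_idx
        )

    # --- SST -------------------------------------------------------------
    if not include_sst:
        return out
    go_trials = [tr for tr in sst_trials if not tr.is_stop]
    stop_trials = [tr for tr in sst_trials if tr.is_stop]

    rng = np.random.default_rng([truth.seed, subject, 3])
    sources = []
    for tr in go_trials:
        sources.append(
            [
                (
                    truth.n1_component,
                    -(g_n1 * truth.n1_uv + rng.normal(0.0, truth.amp_noise_uv)),
                    truth.n1_on_ms,
                    truth.n1_peak_ms,
                    truth.n1_off_ms,
                )
            ]
        )
    out["sst_go"] = _render_epochs(
        rng, truth, trials_to_frame(go_trials), sources, sid, channel_idx=ch_idx
    )

    rng = np.random.default_rng([truth.seed, subject, 4])
    sources = []
    for tr in stop_trials:
        shift = jit + (
            0.0 if tr.outcome == "stop_success" else truth.success_fail_onset_diff_ms
        )
        amp = g_stop * truth.stop_p3_uv + rng.normal(0.0, truth.amp_noise_uv)
        ev = [
            (
                truth.p3_component,
                amp,
                truth.stop_p3_on_ms + shift,
                truth.stop_p3_peak_ms + shift,
                truth.stop_p3_off_ms + shift,
            ),
            # go arrow N1 precedes the stop signal by the SSD
            (
                truth.n1_component,
                -(g_n1 * truth.n1_uv + rng.normal(0.0, truth.amp_noise_uv)),
                truth.n1_on_ms - tr.ssd_ms,
                truth.n1_peak_ms - tr.ssd_ms,
                truth.n1_off_ms - tr.ssd_ms,
            ),
        ]
        sources.append(ev)
    out["sst_stop"] = _render_epochs(
        rng, truth, trials_to_frame(stop_trials), sources, sid, channel_idx=ch_idx
    )
    return out


def gen_cohort_epochs(
    cmo_sequences: Sequence[Sequence[OddballTrial]],
    sst_sequences: Sequence[Sequence[StopTrial]],
    truth: GroundTruth,
    **kwargs,
) -> dict:
    """Generate epochs for a whole cohort (kept in memory; for large
    cohorts iterate `gen_subject_epochs` and reduce per subject)."""
    if len(cmo_sequences) != truth.n_subjects or len(sst_sequences) != truth.n_subjects:
        raise ValueError("one sequence per subject is required")
    subjects = [
        gen_subject_epochs(truth, s, cmo_sequences[s], sst_sequences[s], **kwargs)
        for s in range(truth.n_subjects)
    ]
    return {
        "cmo": [s["cmo"] for s in subjects],
        "cmo_target": [s.get("cmo_target") for s in subjects],
        "sst_go": [s["sst_go"] for s in subjects],
        "sst_stop": [s["sst_stop"] for s in subjects],
        "truth": truth,
    }


def cohort_sequences(
    truth: GroundTruth,
    n_blocks: int = 4,
    trials_per_block: int = 60,
    sst_n_trials: int = 300,
    race: RaceParams | None = None,
) -> tuple[list[list[OddballTrial]], list[list[StopTrial]]]:
    """Per-subject CMO and SST sequences consistent with the ground truth.

    The subject's P3-onset latency jitter is added to the mean SSRT of the
    race, coupling neural onset with stopping speed across the cohort.
    """
    cmo, sst = [], []
    for s in range(truth.n_subjects):
        cmo.append(
            gen_oddball_sequence(
                n_blocks, trials_per_block, seed=np.random.SeedSequence(
                    [truth.seed, s, 101]
                ).generate_state(1)[0],
            )
        )
        sst.append(
            gen_sst_behavior(
                n_trials=sst_n_trials,
                race=race,
                seed=np.random.SeedSequence([truth.seed, s, 102]).generate_state(1)[0],
                ssrt_shift_ms=float(truth.p3_onset_jitter_ms[s]),
            )
        )
    return cmo, sst
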