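"""64-channel extended 10-20 scalp montage used by the synthetic generator.

The analysis montage standardizes to 64 scalp positions covering the
extended 10-20 system.  2-D sensor coordinates come from MNE's bundled
``standard_1020`` montage (top-down projection of the 3-D positions),
so region-of-interest partitions and spatial noise kernels operate on
realistic geometry.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: The 64 scalp channels, anterior to posterior.
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

#: Channels that must exist for the fronto-central / occipital analyses.
REQUIRED_CHANNELS = ("FCz", "Cz", "FC1", "FC2", "C1", "C2", "Fz", "Oz", "O1", "O2")

FRONTOCENTRAL = ("FCz", "Cz", "FC1", "FC2", "C1", "C2")
OCCIPITAL = ("Oz", "O1", "O2")


@lru_cache(maxsize=4)
def _positions_3d(channels: tuple[str, ...]) -> np.ndarray:
    import warnings

    import mne

    with warnings.catch_warnings():
        # montage naming is in flux across MNE releases; the electrode
        # positions themselves are stable
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    missing = [ch for ch in channels if ch not in pos]
    if missing:
        raise KeyError(f"channels not in standard_1020 montage: {missing}")
    return np.array([pos[ch] for ch in channels])


def sensor_layout(channels: tuple[str, ...] = CHANNELS_64) -> np.ndarray:
    """Return per-channel 2-D scalp coordinates (n_channels, 2), meters.

    Uses the (x, y) plane of the 3-D electrode positions, i.e. a simple
    top-down projection, which is adequate for ROI assignment and for the
    spatial correlation kernel of the synthetic sensor noise.
    """
    return _positions_3d(tuple(channels))[:, :2].copy()


def channel_index(channels, names) -> np.ndarray:
    """Indices of `names` within the channel list, erroring on absences."""
    lookup = {ch: i for i, ch in enumerate(channels)}
    try:
        return np.array([lookup[n] for n in names], dtype=int)
    except KeyError as exc:
        raise KeyError(f"channel {exc.args[0]!r} not present in montage") from exc
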