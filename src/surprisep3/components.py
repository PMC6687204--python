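"""Independent-component back-projection, spatiotemporal selection of
the stop-signal P3 component, reconstruction variants, and surprise
refits on reconstructed data.

Decompositions (mixing/unmixing matrices) arrive from outside — from
the synthetic ground truth or from any externally computed blind-source
separation; estimating them is out of scope here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import numpy as np

from . import erp as erp_mod
from . import mapping as mapping_mod
from .montage import FRONTOCENTRAL

log = logging.getLogger(__name__)

SELECTION_WINDOW_MS = (200.0, 300.0)


class SelectionFailure(RuntimeError):
    """No component shows a fronto-central stop-minus-go topography."""


@dataclass
class Decomposition:
    """Linear channel-space decomposition (mixing: channels x components)."""

    subject_id: str
    mixing: np.ndarray
    unmixing: np.ndarray
    component_ids: tuple[int, ...] = None

    def __post_init__(self):
        if self.component_ids is None:
            self.component_ids = tuple(range(self.mixing.shape[1]))
        if self.mixing.shape[1] != self.unmixing.shape[0]:
            raise ValueError("mixing and unmixing disagree on component count")
        if self.mixing.shape[0] != self.unmixing.shape[1]:
            raise ValueError("mixing and unmixing disagree on channel count")

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def activations(self, data: np.ndarray) -> np.ndarray:
        """Component activations, (trials, components, samples)."""
        return np.einsum("kc,tcs->tks", self.unmixing, data)


def decomposition_from_truth(truth, subject: int) -> Decomposition:
    """Square ground-truth decomposition (exactly invertible mixing)."""
    return Decomposition(
        subject_id=f"sub-{subject + 1:02d}",
        mixing=truth.mixing.copy(),
        unmixing=np.linalg.inv(truth.mixing),
    )


def backproject(decomp: Decomposition, epochs, subset) -> "object":
    """Reconstruct channel data from a component subset.

    ``subset=()`` gives all-zero data; the full subset reproduces the
    input exactly when the decomposition spans channel space.
    """
    subset = tuple(subset)
    unknown = [c for c in subset if c not in decomp.component_ids]
    if unknown:
        raise KeyError(f"unknown component ids: {unknown}")
    pos = [decomp.component_ids.index(c) for c in subset]
    if not pos:
        data = np.zeros_like(epochs.data)
    else:
        M = decomp.mixing[:, pos]
        U = decomp.unmixing[pos, :]
        data = np.einsum("ck,kd,tds->tcs", M, U, epochs.data, optimize=True)
    return replace(epochs, data=data)


# ---------------------------------------------------------------------------
# 9-ROI scalp partition
# ---------------------------------------------------------------------------

_ROW_BY_PREFIX = {
    "Fp": "anterior", "AF": "anterior", "F": "anterior",
    "FT": "central", "FC": "central", "C": "central", "T": "central",
    "TP": "posterior", "CP": "posterior", "P": "posterior",
    "PO": "posterior", "O": "posterior", "I": "posterior",
}


def _row_col(label: str) -> tuple[str, str]:
    m = re.fullmatch(r"([A-Za-z]+?)(z|\d+)", label)
    if not m:
        raise ValueError(f"cannot parse channel label {label!r}")
    prefix, suffix = m.group(1), m.group(2)
    if prefix not in _ROW_BY_PREFIX:
        raise ValueError(f"unknown channel prefix {prefix!r}")
    row = _ROW_BY_PREFIX[prefix]
    if suffix == "z" or int(suffix) in (1, 2):
        col = "midline"
    elif int(suffix) % 2 == 1:
        col = "left"
    else:
        col = "right"
    return row, col


@dataclass
class RoiPartition:
    """3 x 3 grid of scalp regions (anterior/central/posterior by
    left/midline/right) with every channel in exactly one cell."""

    channel_labels: tuple[str, ...]
    cells: dict = None

    def __post_init__(self):
        if self.cells is None:
            self.cells = {}
            for i, ch in enumerate(self.channel_labels):
                self.cells.setdefault(_row_col(ch), []).append(i)
        fc = set(self.channel_labels[i] for i in self.cells[("central", "midline")])
        if fc != set(FRONTOCENTRAL):
            raise ValueError(
                f"fronto-central cell {sorted(fc)} deviates from expected membership"
            )

    @property
    def frontocentral(self) -> list[int]:
        return self.cells[("central", "midline")]

    def cell_means(self, topo: np.ndarray) -> dict:
        return {cell: float(topo[idx].mean()) for cell, idx in self.cells.items()}


# ---------------------------------------------------------------------------
# stop-P3 component selection
# ---------------------------------------------------------------------------

def select_stop_p3_ic(
    decomp: Decomposition,
    stop_epochs,
    go_epochs,
    roi: RoiPartition | None = None,
    window_ms: tuple[float, float] = SELECTION_WINDOW_MS,
) -> dict:
    """Two-step spatiotemporal selection of the stop-signal P3 component.

    Step 1 keeps components whose back-projected stop-minus-go
    difference topography (mean over `window_ms`) peaks in the
    fronto-central ROI cell.  Step 2 returns, among the keepers, the
    component whose fronto-central mean time-course correlates most
    highly over the window with the all-component channel-space
    difference ERP in the same ROI.

    Raises SelectionFailure when no component passes step 1.
    """
    if decomp.n_components < 1:
        raise ValueError("empty decomposition")
    roi = roi or RoiPartition(tuple(stop_epochs.channel_labels))
    t = stop_epochs.times_ms
    win = (t >= window_ms[0]) & (t <= window_ms[1])
    diff = erp_mod.condition_erp(stop_epochs) - erp_mod.condition_erp(go_epochs)
    act_diff = decomp.unmixing @ diff                    # components x samples

    candidates = []
    for k, cid in enumerate(decomp.component_ids):
        topo = decomp.mixing[:, k] * act_diff[k, win].mean()
        means = roi.cell_means(topo)
        if max(means, key=means.get) == ("central", "midline"):
            candidates.append(cid)
    if not candidates:
        raise SelectionFailure("no component with fronto-central stop-minus-go positivity")

    fc = roi.frontocentral
    target = diff[fc][:, win].mean(axis=0)
    correlations = {}
    for cid in candidates:
        k = decomp.component_ids.index(cid)
        comp_tc = np.outer(decomp.mixing[:, k], act_diff[k])[fc][:, win].mean(axis=0)
        if comp_tc.std() == 0 or target.std() == 0:
            correlations[cid] = -np.inf
        else:
            correlations[cid] = float(np.corrcoef(comp_tc, target)[0, 1])
    selected = max(correlations, key=correlations.get)
    return {
        "selected": selected,
        "step1_candidates": candidates,
        "step2_correlations": correlations,
    }


def explained_variance(decomp: Decomposition, epochs) -> np.ndarray:
    """Per-component variance of its back-projected channel signal."""
    act = decomp.activations(epochs.data)                # trials x comps x samples
    out = np.empty(decomp.n_components)
    for k in range(decomp.n_components):
        proj = decomp.mixing[:, k][None, :, None] * act[:, k][:, None, :]
        out[k] = proj.var()
    return out


def reconstruct_variants(
    decomp: Decomposition, epochs, selected: int, seed: int = 0
) -> dict:
    """The four reconstruction variants used as surprise-refit inputs.

    * ``selected_only`` — only the stop-P3 component,
    * ``all_but_selected`` — everything except it,
    * ``random_single`` — one seeded random non-selected component,
    * ``max_residual_single`` — the non-selected component explaining
      the most channel-data variance once the selected one is removed.
    """
    others = [c for c in decomp.component_ids if c != selected]
    variants = {"selected_only": backproject(decomp, epochs, [selected])}
    if not others:
        log.warning("single-component decomposition: control variants unavailable")
        return variants
    variants["all_but_selected"] = backproject(decomp, epochs, others)
    rng = np.random.default_rng(seed)
    variants["random_single"] = backproject(
        decomp, epochs, [others[rng.integers(len(others))]]
    )
    ev = explained_variance(decomp, epochs)
    order = {c: ev[decomp.component_ids.index(c)] for c in others}
    variants["max_residual_single"] = backproject(
        decomp, epochs, [max(order, key=order.get)]
    )
    return variants


def group_variant_betas(
    betas_by_variant: dict[str, list], family_alpha: float = 0.01
) -> dict[str, mapping_mod.GroupStatMap]:
    """Group-level maps per reconstruction variant with FDR pooled over
    all included variant sets at `family_alpha`."""
    maps = {}
    for name, betas in betas_by_variant.items():
        b = np.stack([m.beta for m in betas])
        t, p = mapping_mod._cellwise_t(b)
        maps[name] = mapping_mod.GroupStatMap(
            contrast=f"refit:{name}",
            t=t, p=p, mean_beta=np.nanmean(b, axis=0),
            channel_labels=betas[0].channel_labels,
            centers_ms=betas[0].centers_ms,
        )
    pooled = np.concatenate([m.p.ravel() for m in maps.values()])
    alpha_adj = mapping_mod.bh_adjusted_alpha(pooled[np.isfinite(pooled)], family_alpha)
    for m in maps.values():
        m.apply_alpha(alpha_adj)
    return maps


def refit_on_reconstruction(
    variant_epochs: dict[str, list],
    series_per_subject: list,
    family_alpha: float = 0.01,
    spec: mapping_mod.WindowSpec = mapping_mod.WindowSpec(),
) -> dict[str, mapping_mod.GroupStatMap]:
    """Refit the winning surprise model on each reconstruction variant.

    `variant_epochs` maps variant name -> per-subject CMO epoch sets
    (unexpected-cue trials); `series_per_subject` are the matching
    surprise series.  FDR is pooled over all included variant sets at
    `family_alpha`, as in the main mapping analysis.
    """
    if not variant_epochs:
        raise ValueError("no variants supplied")
    n_sub = len(series_per_subject)
    if any(len(v) != n_sub for v in variant_epochs.values()):
        raise ValueError("every variant needs one epoch set per subject")

    betas_by_variant = {}
    for name, per_subject in variant_epochs.items():
        betas = []
        for s, ep in enumerate(per_subject):
            w = mapping_mod.window_average(ep, spec)
            betas.append(
                mapping_mod.fit_surprise_map(
                    w,
                    series_per_subject[s],
                    subject_id=ep.subject_id,
                    channel_labels=tuple(ep.channel_labels),
                    centers_ms=spec.centers_ms,
                )
            )
        betas_by_variant[name] = betas
    return group_variant_betas(betas_by_variant, family_alpha)
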