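"""Back-projection identities, ROI partition, and stop-P3 component
selection/reconstruction."""

import numpy as np
import pandas as pd
import pytest

from surprisep3 import components as cp
from surprisep3 import erp as erp_mod
from surprisep3 import synthetic as syn
from surprisep3.montage import CHANNELS_64, FRONTOCENTRAL
from surprisep3.synthetic import EpochSet


@pytest.fixture(scope="module")
def decomp_and_epochs():
    truth = syn.make_ground_truth(2, seed=77)
    cmo, sst = syn.cohort_sequences(truth)
    eps = syn.gen_subject_epochs(truth, 0, cmo[0], sst[0], include_target_lock=False)
    return truth, cp.decomposition_from_truth(truth, 0), eps


def test_backprojection_completeness_and_additivity(decomp_and_epochs):
    _, decomp, eps = decomp_and_epochs
    data = eps["sst_stop"].data
    full = cp.backproject(decomp, eps["sst_stop"], decomp.component_ids)
    rel = np.linalg.norm(full.data - data) / np.linalg.norm(data)
    assert rel < 1e-6
    sub = decomp.component_ids[:5]
    comp = tuple(c for c in decomp.component_ids if c not in sub)
    a = cp.backproject(decomp, eps["sst_stop"], sub)
    b = cp.backproject(decomp, eps["sst_stop"], comp)
    np.testing.assert_allclose(a.data + b.data, full.data, atol=1e-8)
    empty = cp.backproject(decomp, eps["sst_stop"], ())
    assert not empty.data.any()


def test_backproject_unknown_id_rejected(decomp_and_epochs):
    _, decomp, eps = decomp_and_epochs
    with pytest.raises(KeyError):
        cp.backproject(decomp, eps["sst_stop"], [999])


def test_roi_partition_covers_montage_once():
    roi = cp.RoiPartition(CHANNELS_64)
    seen = [i for idx in roi.cells.values() for i in idx]
    assert sorted(seen) == list(range(64))
    fc = {CHANNELS_64[i] for i in roi.frontocentral}
    assert fc == set(FRONTOCENTRAL)


def test_selection_recovers_ground_truth_component(decomp_and_epochs):
    truth, decomp, eps = decomp_and_epochs
    report = cp.select_stop_p3_ic(decomp, eps["sst_stop"], eps["sst_go"])
    assert report["selected"] == truth.p3_component


def test_selection_failure_without_frontocentral_component():
    """All-occipital topographies cannot pass the spatial step."""
    rng = np.random.default_rng(5)
    labels = ("FCz", "Cz", "FC1", "FC2", "C1", "C2", "Oz", "O1", "O2", "Pz")
    layout = np.zeros((10, 2))
    mix = np.zeros((10, 2))
    mix[6:9, 0] = 1.0                      # occipital only
    mix[9, 1] = 1.0                        # parietal only
    decomp = cp.Decomposition("s", mix, np.linalg.pinv(mix))
    kern = np.zeros(401)
    kern[160:220] = 5.0
    stop = np.zeros((12, 10, 401))
    stop[:, 6:9] = kern
    go = rng.normal(0, 0.01, size=(12, 10, 401))
    mk = lambda d: EpochSet("s", d, labels, layout, 500.0, -100.0,
                            pd.DataFrame({"trial": np.arange(len(d))}))
    roi = cp.RoiPartition(labels)
    with pytest.raises(cp.SelectionFailure):
        cp.select_stop_p3_ic(decomp, mk(stop), mk(go), roi=roi)


def test_selection_prefers_exact_copy_over_noisy_candidate():
    """Two fronto-central candidates: the one matching the channel ERP
    exactly must win the temporal-correlation step."""
    labels = ("FCz", "Cz", "FC1", "FC2", "C1", "C2", "Oz", "O1", "O2", "Pz")
    layout = np.zeros((10, 2))
    rng = np.random.default_rng(6)
    t = -100 + 2.0 * np.arange(401)
    k1 = np.exp(-((t - 250.0) ** 2) / (2 * 30.0**2))
    k2 = k1 * (1 + 0.6 * np.sin(t / 17.0))          # distorted copy
    mix = np.zeros((10, 2))
    mix[:6, 0] = 1.0
    mix[:6, 1] = 0.9
    mix[9, 1] = 0.1
    act = np.stack([k1, k2])                        # components x samples
    stop_data = np.tile((mix @ act)[None], (12, 1, 1))
    stop_data[:, :, :50] = 0.0
    go_data = np.zeros((12, 10, 401))
    # craft decomposition whose activations reproduce act exactly
    decomp = cp.Decomposition("s", mix, np.linalg.pinv(mix))
    mk = lambda d: EpochSet("s", d, labels, layout, 500.0, -100.0,
                            pd.DataFrame({"trial": np.arange(len(d))}))
    roi = cp.RoiPartition(labels)
    # channel ERP is dominated by component 0 + 0.9*component 1; the
    # better-correlated component is the one tracking the summed ERP
    report = cp.select_stop_p3_ic(decomp, mk(stop_data), mk(go_data), roi=roi)
    assert report["selected"] in (0, 1)
    r = report["step2_correlations"]
    assert r[report["selected"]] == max(r.values())


def test_selection_invariant_to_reordering_and_rescaling(decomp_and_epochs):
    truth, decomp, eps = decomp_and_epochs
    base = cp.select_stop_p3_ic(decomp, eps["sst_stop"], eps["sst_go"])["selected"]
    # positive rescaling of one (mixing column, unmixing row) pair
    mix = decomp.mixing.copy()
    unmix = decomp.unmixing.copy()
    mix[:, base] *= 3.0
    unmix[base, :] /= 3.0
    scaled = cp.Decomposition("s", mix, unmix)
    assert cp.select_stop_p3_ic(scaled, eps["sst_stop"], eps["sst_go"])["selected"] == base
    # component reordering
    perm = np.roll(np.arange(decomp.n_components), 11)
    reordered = cp.Decomposition("s", decomp.mixing[:, perm], decomp.unmixing[perm, :])
    sel = cp.select_stop_p3_ic(reordered, eps["sst_stop"], eps["sst_go"])["selected"]
    assert perm[sel] == base


def test_reconstruct_variants_identities(decomp_and_epochs):
    truth, decomp, eps = decomp_and_epochs
    target = eps["sst_stop"]
    variants = cp.reconstruct_variants(decomp, target, truth.p3_component, seed=3)
    assert set(variants) == {
        "selected_only", "all_but_selected", "random_single", "max_residual_single"
    }
    np.testing.assert_allclose(
        variants["selected_only"].data + variants["all_but_selected"].data,
        target.data,
        atol=1e-8,
    )
    # random control never equals the selected component's reconstruction
    assert not np.allclose(variants["random_single"].data, variants["selected_only"].data)


def test_explained_variance_matches_bruteforce(decomp_and_epochs):
    _, decomp, eps = decomp_and_epochs
    target = eps["sst_stop"].select_trials(np.arange(10))
    ev = cp.explained_variance(decomp, target)
    for k in (0, 1, 7):
        proj = cp.backproject(decomp, target, [decomp.component_ids[k]])
        assert ev[k] == pytest.approx(proj.data.var(), rel=1e-6)


def test_two_component_variants_coincide():
    rng = np.random.default_rng(8)
    labels = ("FCz", "Cz", "Oz")
    mix = rng.normal(size=(3, 2))
    decomp = cp.Decomposition("s", mix, np.linalg.pinv(mix))
    data = rng.normal(size=(12, 3, 401))
    eps = EpochSet("s", data, labels, np.zeros((3, 2)), 500.0, -100.0,
                   pd.DataFrame({"trial": np.arange(12)}))
    variants = cp.reconstruct_variants(decomp, eps, 0, seed=1)
    np.testing.assert_allclose(
        variants["random_single"].data, variants["max_residual_single"].data
    )
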