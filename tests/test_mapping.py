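"""Window averaging, robust regression, and multiple-comparison tests."""

import numpy as np
import pytest
from scipy import stats

from surprisep3 import mapping as mp
from surprisep3.synthetic import EpochSet
import pandas as pd


def _epochs_from_array(data):
    n_tr, n_ch, _ = data.shape
    return EpochSet(
        subject_id="s",
        data=data,
        channel_labels=tuple(f"C{i}" for i in range(n_ch)),
        sensor_layout=np.zeros((n_ch, 2)),
        sfreq_hz=500.0,
        tmin_ms=-100.0,
        events=pd.DataFrame({"trial": np.arange(n_tr)}),
    )


def test_window_average_constant_epoch_is_zero():
    eps = _epochs_from_array(np.full((3, 2, 401), 7.5))
    w = mp.window_average(eps)
    assert w.shape == (3, 2, 10)
    np.testing.assert_allclose(w, 0.0, atol=1e-12)


def test_window_average_of_linear_ramp_matches_closed_form():
    # v(t) = t; baseline mean over [-100, 0] is -50, so every window's
    # cell equals its center + 50 (symmetric mean of a linear function)
    t = -100.0 + 2.0 * np.arange(401)
    eps = _epochs_from_array(np.tile(t, (2, 1, 1)))
    w = mp.window_average(eps)
    for j, c in enumerate(mp.WindowSpec().centers_ms):
        np.testing.assert_allclose(w[:, :, j], c + 50.0, atol=1e-9)


def test_window_average_shape_for_48_trials():
    eps = _epochs_from_array(np.random.default_rng(0).normal(size=(48, 1, 401)))
    assert mp.window_average(eps)[:, 0, :].shape == (48, 10)


def test_window_spec_exceeding_epoch_rejected():
    eps = _epochs_from_array(np.zeros((2, 1, 200)))   # epoch ends at 298 ms
    with pytest.raises(ValueError):
        mp.window_average(eps)


# --- robust regression -------------------------------------------------------

def _fit_beta(x, y):
    ser = pd.DataFrame({"surprise": x, "model_id": "separate"})
    return mp.fit_surprise_map(y[:, None, None], ser, "s", ("FCz",)).beta[0, 0]


def test_identity_regression_gives_unit_beta(rng):
    x = rng.normal(size=40)
    assert _fit_beta(x, x.copy()) == pytest.approx(1.0, abs=1e-6)
    assert _fit_beta(x, -x) == pytest.approx(-1.0, abs=1e-6)


def test_robust_beta_resists_gross_outlier(rng):
    x = rng.normal(size=40)
    y = x.copy()
    y[5] += 10 * (x.max() - x.min())
    xz = (x - x.mean()) / x.std(ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    ols = np.polyfit(xz, yz, 1)[0]
    robust = _fit_beta(x, y)
    assert abs(robust - 1.0) < abs(ols - 1.0)


def test_robust_slopes_agree_with_statsmodels_rlm(rng):
    import statsmodels.api as sm

    x = rng.normal(size=60)
    Y = 0.5 * x[:, None] + rng.normal(size=(60, 5))
    Y[3, 2] += 8.0
    ours = mp.robust_slopes(x, Y)
    X = sm.add_constant(x)
    for j in range(5):
        ref = sm.RLM(Y[:, j], X, M=sm.robust.norms.TukeyBiweight(4.685)).fit(
            scale_est="mad"
        )
        assert ours[j] == pytest.approx(ref.params[1], abs=5e-3)


def test_zero_variance_response_yields_absent_beta(rng):
    x = rng.normal(size=20)
    ser = pd.DataFrame({"surprise": x, "model_id": "separate"})
    y = np.full((20, 1, 1), 3.0)
    assert np.isnan(mp.fit_surprise_map(y, ser, "s", ("FCz",)).beta[0, 0])


def test_too_few_trials_rejected(rng):
    ser = pd.DataFrame({"surprise": rng.normal(size=5), "model_id": "separate"})
    with pytest.raises(ValueError):
        mp.fit_surprise_map(rng.normal(size=(5, 1, 1)), ser)


# --- multiple comparisons ----------------------------------------------------

def test_bh_worked_example():
    alpha = mp.bh_adjusted_alpha(np.array([0.001, 0.008, 0.039, 0.041]), 0.05)
    assert alpha == pytest.approx(0.041)


def test_bh_global_null_yields_empty_mask():
    assert mp.bh_adjusted_alpha(np.ones(100), 0.05) == 0.0


def _bh_bruteforce(p, q):
    """Largest p(k) with p(k) <= k q / m by explicit enumeration."""
    ps = np.sort(p)
    best = 0.0
    for k, val in enumerate(ps, start=1):
        if val <= k * q / len(ps):
            best = val
    return best


def test_bh_matches_bruteforce_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(1000):
        m = int(rng.integers(1, 60))
        p = rng.random(m) ** rng.uniform(0.5, 3.0)
        q = float(rng.choice([0.01, 0.05, 0.1]))
        thr = mp.bh_adjusted_alpha(p, q)
        assert thr == pytest.approx(_bh_bruteforce(p, q))
        reject = multipletests(p, alpha=q, method="fdr_bh")[0]
        np.testing.assert_array_equal(p <= thr, reject)


@pytest.mark.parametrize(
    "alpha, m, expected", [(0.05, 8, 0.00625), (0.01, 1, 0.01), (0.05, 2, 0.025)]
)
def test_bonferroni(alpha, m, expected):
    assert mp.bonferroni_alpha(alpha, m) == pytest.approx(expected)
    assert round(mp.bonferroni_alpha(0.05, 8), 4) == 0.0063


def test_bonferroni_rejects_bad_m():
    with pytest.raises(ValueError):
        mp.bonferroni_alpha(0.05, 0)


def test_group_and_compare_bookkeeping(rng):
    n_sub, n_ch, n_win = 6, 64, 10
    mk = lambda mid: [
        mp.BetaMap(f"s{i}", mid, rng.normal(size=(n_ch, n_win)),
                   tuple(f"C{c}" for c in range(n_ch)),
                   tuple(float(c) for c in range(50, 501, 50)), 48)
        for i in range(n_sub)
    ]
    maps = mp.group_and_compare(mk("separate"), mk("common"), 0.01)
    assert maps["model1_vs_model2"].p.size == 640
    assert len(maps) == 3
    alphas = {m.adjusted_alpha for m in maps.values()}
    assert len(alphas) == 1                  # single pooled threshold
    for m in maps.values():
        np.testing.assert_array_equal(m.sig_mask, m.p <= m.adjusted_alpha)


# --- RT regression -----------------------------------------------------------

def test_rt_fit_recovers_positive_slope_and_null_is_centered(rng):
    betas_pos, betas_null = [], []
    for s in range(30):
        x = rng.uniform(0.1, 1.0, size=48)
        ser = pd.DataFrame({"surprise": x, "model_id": "separate"})
        rt_pos = 450 + 80 * x + rng.normal(0, 60, size=48)
        rt_null = 450 + rng.normal(0, 60, size=48)
        betas_pos.append(mp.fit_rt_surprise(ser, rt_pos))
        betas_null.append(mp.fit_rt_surprise(ser, rt_null))
    assert mp.group_rt_test(np.array(betas_pos))["p"] < 0.001
    assert mp.group_rt_test(np.array(betas_pos))["t"] > 0
    assert abs(np.nanmean(betas_null)) < 0.1


def test_rt_fit_degenerate_inputs(rng):
    x = rng.uniform(0, 1, size=20)
    ser = pd.DataFrame({"surprise": x, "model_id": "separate"})
    assert np.isnan(mp.fit_rt_surprise(ser, np.full(20, 500.0)))
    few = np.full(20, np.nan)
    few[:5] = 400.0
    assert np.isnan(mp.fit_rt_surprise(ser, few))
    blocks = np.repeat([1, 2, 3, 4], 5)
    out = mp.fit_rt_surprise(ser, 400 + 50 * x, blocks, subset="first_half")
    assert np.isfinite(out)
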