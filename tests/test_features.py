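"""Windowed irregularity features against brute-force recomputation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afdetect import (
    FEATURE_NAMES,
    InvalidInputError,
    RRSeries,
    WindowConfig,
    extract_features,
    feature_vector,
    fhr_features,
    hr_from_rr,
    nonlinear_features,
    robust_features,
    time_domain_features,
)
from afdetect.features import expected_turning_points
from conftest import random_rr_windows
from oracles import bf_features, bf_quantile

CFG = WindowConfig()


@pytest.mark.parametrize("rr, hr", [(1000.0, 60.0), (500.0, 120.0), (600.0, 100.0)])
def test_hr_from_rr_exact(rr, hr):
    assert hr_from_rr(np.array([rr]))[0] == hr


def test_hr_from_rr_rejects_nonpositive():
    with pytest.raises(InvalidInputError, match="beat 2"):
        hr_from_rr(np.array([800.0, 810.0, 0.0]))


@pytest.mark.parametrize(
    "value, expected_prp", [(150.0, 1.0), (100.0, 0.0), (120.0, 1.0), (160.0, 1.0)]
)
def test_robust_constant_window(value, expected_prp):
    """Constant windows: med = qnt = value, mad = 0; PRP band is inclusive."""
    med, mad, qnt, prp = robust_features(np.full(21, value))
    assert (med, mad, qnt) == (value, 0.0, value)
    assert prp == expected_prp


def test_robust_quantile_matches_order_statistics():
    hr = np.arange(60.0, 81.0)  # 21 values 60..80
    med, _, qnt, _ = robust_features(hr)
    assert med == 70.0
    assert qnt == pytest.approx(bf_quantile(hr, 0.7), rel=1e-12)


def test_time_domain_trivial_windows():
    const = np.full(21, 750.0)
    mean_hr, std_hr, rmssd, pnn50 = time_domain_features(60000.0 / const, const)
    assert (mean_hr, std_hr, rmssd, pnn50) == (80.0, 0.0, 0.0, 0.0)

    alt = np.where(np.arange(21) % 2 == 0, 700.0, 800.0)
    _, _, rmssd, pnn50 = time_domain_features(60000.0 / alt, alt)
    assert rmssd == pytest.approx(100.0)
    assert pnn50 == pytest.approx(100.0)


def test_nonlinear_trivial_windows():
    assert nonlinear_features(np.full(21, 800.0)) == (0.0, 0.0, 0.0)
    monotone = np.linspace(600.0, 900.0, 21)
    *_, tpr = nonlinear_features(monotone)
    assert tpr == 0.0


def test_wrong_window_length_is_contract_error():
    with pytest.raises(ValueError, match="length 21"):
        robust_features(np.full(20, 100.0))
    with pytest.raises(ValueError, match="length 21"):
        nonlinear_features(np.full(22, 800.0))


def test_turning_point_count_matches_random_expectation(rng):
    """Mean turning points over random permutations approaches (2N-4)/3.

    The sampling SD of a single window's count is sqrt((16N-29)/90); the
    Monte Carlo mean over 10^4 permutations is compared within 4 standard
    errors.
    """
    n = 21
    base = rng.permutation(np.linspace(400.0, 1200.0, n))
    n_perm = 10_000
    counts = np.empty(n_perm)
    expected = expected_turning_points(n)
    for i in range(n_perm):
        w = rng.permutation(base)
        *_, tpr = nonlinear_features(w)
        counts[i] = tpr * expected
    se = np.sqrt((16 * n - 29) / 90) / np.sqrt(n_perm)
    assert abs(counts.mean() - expected) < 4 * se


def test_fhr_trivial_and_alternating():
    const = np.full(21, 800.0)
    assert fhr_features(const, 60000.0 / const) == (0.0, 0.0, 0.0, 0.0)

    # alternating 800/820: all d_i = -/+ 20/1620 in equal numbers
    alt = np.where(np.arange(21) % 2 == 0, 800.0, 820.0)
    d_mag = 20.0 / 1620.0
    di_yeh, stv_zug, stv_huey, sti_haan = fhr_features(alt, 60000.0 / alt)
    assert di_yeh == pytest.approx(d_mag * np.sqrt(20.0 / 19.0), rel=1e-12)
    assert stv_zug == pytest.approx(0.0, abs=1e-15)  # |D_i| all equal their median
    assert stv_huey > 0.0


def test_extract_shapes_and_masking():
    fm = extract_features(RRSeries("a", np.full(41, 800.0)))
    assert fm.n_valid == 21
    assert (~fm.valid_mask).sum() == 20
    assert not fm.valid_mask[:10].any() and not fm.valid_mask[-10:].any()

    with pytest.warns(UserWarning, match="no valid beats"):
        empty = extract_features(RRSeries("b", np.full(15, 800.0)))
    assert empty.n_valid == 0


def test_database_wide_exclusion_count(rng):
    """25 signals of any lengths >= 21 lose exactly 25 x 20 = 500 beats."""
    masked = 0
    for i in range(25):
        n = int(rng.integers(21, 200))
        fm = extract_features(RRSeries(f"s{i}", rng.uniform(400, 1200, n)))
        masked += int((~fm.valid_mask).sum())
    assert masked == 500


def test_features_match_bruteforce():
    """Vectorised extraction == loop-based oracle to 1e-9 relative."""
    for w in random_rr_windows(200, seed=42):
        got = feature_vector(w)
        want = bf_features(w)
        for name, g in zip(FEATURE_NAMES, got):
            assert g == pytest.approx(want[name], rel=1e-9, abs=1e-12), name


def test_extract_rows_equal_scalar_path(rng):
    rr = RRSeries("x", rng.uniform(350, 1200, 60))
    fm = extract_features(rr)
    for row, beat in zip(fm.X, fm.beat_index):
        np.testing.assert_allclose(
            row, feature_vector(rr.rr_ms[beat - 10 : beat + 11]), rtol=1e-12
        )


def test_shift_and_scale_behaviour(rng):
    w = rng.uniform(500, 1000, 21)
    names = list(FEATURE_NAMES)
    base = dict(zip(names, feature_vector(w)))
    shifted = dict(zip(names, feature_vector(w + 300.0)))
    for f in ("rmssd", "pnn50", "sd1", "tpr"):
        assert shifted[f] == pytest.approx(base[f], rel=1e-9)
    scaled = dict(zip(names, feature_vector(w * 1.7)))
    for f in ("rmssd", "sd1", "sd2"):
        assert scaled[f] == pytest.approx(1.7 * base[f], rel=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=250.0, max_value=3000.0, allow_nan=False),
        min_size=21,
        max_size=21,
    )
)
def test_all_features_finite_for_positive_rr(window):
    assert np.isfinite(feature_vector(np.array(window))).all()


def test_af_windows_have_larger_dispersion(small_db):
    """AF windows carry strictly larger RMSSD/Yeh/Zugaib/de Haan on average."""
    per_class = {1: [], -1: []}
    for s in small_db:
        fm = extract_features(s)
        y = fm.y
        for cls in (1, -1):
            per_class[cls].append(fm.X[y == cls])
    af = np.vstack(per_class[1])
    naf = np.vstack(per_class[-1])
    idx = {n: i for i, n in enumerate(FEATURE_NAMES)}
    for f in ("rmssd", "di_yeh", "stv_zug", "sti_haan"):
        assert af[:, idx[f]].mean() > naf[:, idx[f]].mean()
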