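"""EFR-FFQ pairing, rank correlation, Bland-Altman, PCoA and Procrustes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import pdist, squareform

from twindiet.concordance import (
    bland_altman,
    nutrient_configuration,
    pair_closest,
    pcoa,
    procrustes_test,
    spearman_matrix,
)


# --- pairing ----------------------------------------------------------------


def _profiles(rows, date_col, id_col):
    df = pd.DataFrame(rows, columns=["participant_id", date_col, "energy_kcal"])
    df[id_col] = [f"{id_col}{i}" for i in range(len(df))]
    return df


def test_pair_closest_prefers_shortest_gap():
    efr = _profiles(
        [["P1", "2014-01-01", 1800.0], ["P1", "2015-02-05", 1900.0]], "record_date", "r"
    )
    ffq = _profiles([["P1", "2014-01-31", 1700.0]], "ffq_date", "q")
    paired = pair_closest(efr, ffq)
    assert paired.efr.loc[0, "record_date"] == "2014-01-01"  # 30 < ~370 days
    assert paired.days_between[0] == 30


def test_pair_closest_identity_and_missing_ffq_omitted():
    efr = _profiles([["P1", "2014-01-01", 1800.0], ["P2", "2014-01-01", 2000.0]],
                    "record_date", "r")
    ffq = _profiles([["P1", "2014-06-01", 1700.0]], "ffq_date", "q")
    paired = pair_closest(efr, ffq)
    assert paired.participant_ids == ["P1"]


def test_pair_closest_matches_brute_force():
    rng = np.random.default_rng(4)
    rows_e, rows_f = [], []
    for pid in ["P1", "P2", "P3", "P4", "P5"]:
        for _ in range(int(rng.integers(1, 4))):
            rows_e.append([pid, f"201{rng.integers(3, 8)}-0{rng.integers(1, 9)}-15", 1800.0])
        for _ in range(int(rng.integers(1, 3))):
            rows_f.append([pid, f"201{rng.integers(3, 8)}-0{rng.integers(1, 9)}-20", 1700.0])
    efr = _profiles(rows_e, "record_date", "r")
    ffq = _profiles(rows_f, "ffq_date", "q")
    paired = pair_closest(efr, ffq)
    for i, pid in enumerate(paired.participant_ids):
        gaps = [
            abs((pd.Timestamp(e) - pd.Timestamp(f)).days)
            for e in efr[efr.participant_id == pid]["record_date"]
            for f in ffq[ffq.participant_id == pid]["ffq_date"]
        ]
        assert paired.days_between[i] == min(gaps)


# --- Spearman ---------------------------------------------------------------


def _paired_frame(x, y):
    from twindiet.concordance import PairedProfiles

    return PairedProfiles(
        participant_ids=list(range(len(x))),
        efr=pd.DataFrame({"v": x}),
        ffq=pd.DataFrame({"v": y}),
        days_between=np.zeros(len(x)),
    )


def test_spearman_monotone_invariance():
    x = np.linspace(0.1, 3, 12)
    assert spearman_matrix(_paired_frame(x, np.exp(x)), ["v"]).loc[0, "rho"] == pytest.approx(1.0)
    assert spearman_matrix(_paired_frame(x, -x), ["v"]).loc[0, "rho"] == pytest.approx(-1.0)


def test_spearman_matches_rank_formula_with_ties():
    # independent oracle: Pearson correlation of mid-ranks
    x = np.array([3.0, 1, 4, 1, 5, 9, 2, 6, 5, 3])
    y = np.array([2.0, 7, 1, 8, 2, 8, 1, 8, 2, 8])
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    expected = np.corrcoef(rx, ry)[0, 1]
    got = spearman_matrix(_paired_frame(x, y), ["v"]).loc[0, "rho"]
    assert got == pytest.approx(expected)


def test_spearman_constant_column_reported_missing():
    out = spearman_matrix(_paired_frame(np.ones(8), np.arange(8.0)), ["v"])
    assert np.isnan(out.loc[0, "rho"])


# --- Bland-Altman -----------------------------------------------------------


def test_bland_altman_identity_and_shift():
    x = np.array([1.0, 2, 3, 4])
    ident = bland_altman(x, x)
    assert ident.mean_diff == 0 and ident.loa_low == 0 and ident.loa_high == 0
    shifted = bland_altman(x, x + 5)
    assert shifted.mean_diff == pytest.approx(-5.0)  # x - y convention
    assert shifted.sd_diff == pytest.approx(0.0)


def test_bland_altman_limits_hand_calculation():
    x = np.array([10.0, 12, 9, 14, 11, 13])
    y = np.array([11.0, 11, 10, 12, 12, 12])
    d = x - y
    res = bland_altman(x, y)
    assert res.mean_diff == pytest.approx(d.mean())
    assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
    assert np.allclose(res.averages, (x + y) / 2)
    with pytest.raises(ValueError):
        bland_altman(x, y[:-1])


# --- PCoA -------------------------------------------------------------------


def test_pcoa_recovers_collinear_spacing():
    pts = np.array([[0.0], [3.0], [7.0]])
    D = squareform(pdist(pts))
    coords = pcoa(D)
    assert coords.shape[1] == 1
    got = np.sort(pdist(coords[:, :1]))
    assert np.allclose(got, np.sort(pdist(pts)))


def test_pcoa_round_trip_euclidean_configuration():
    rng = np.random.default_rng(0)
    pts = rng.standard_normal((25, 2))
    coords = pcoa(squareform(pdist(pts)), k=2)
    res = procrustes_test(pts, coords, n_perm=49, seed=1)
    assert res.m2 == pytest.approx(0.0, abs=1e-10)


def test_pcoa_duplicate_points_coincide():
    pts = np.array([[0.0, 0], [1, 1], [1, 1], [3, 0]])
    coords = pcoa(squareform(pdist(pts)))
    assert np.allclose(coords[1], coords[2], atol=1e-8)


def test_pcoa_rejects_asymmetric_input():
    with pytest.raises(ValueError):
        pcoa(np.array([[0.0, 1], [2, 0]]))


def test_pcoa_agrees_with_reference_implementation():
    # independent oracle: scikit-bio's classical PCoA on the same distances
    from skbio.stats.ordination import pcoa as skbio_pcoa

    rng = np.random.default_rng(5)
    pts = rng.standard_normal((15, 4))
    D = squareform(pdist(pts))
    ours = pcoa(D)
    ref = skbio_pcoa(D, number_of_dimensions=ours.shape[1]).samples.to_numpy()
    res = procrustes_test(ours, ref, n_perm=49, seed=0)
    assert res.m2 == pytest.approx(0.0, abs=1e-8)


# --- Procrustes -------------------------------------------------------------


def test_identical_configurations_hit_permutation_floor():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((60, 4))
    res = procrustes_test(X, X, n_perm=999, seed=3)
    assert res.m2 == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1 / 1000)


def test_similarity_invariance():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((40, 3))
    Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    Y = 2.7 * (X @ Q) + np.array([5.0, -3.0, 11.0])
    res = procrustes_test(X, Y, n_perm=99, seed=0)
    assert res.m2 == pytest.approx(0.0, abs=1e-10)


def test_m2_matches_scipy_disparity():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((30, 5))
    Y = X @ np.linalg.qr(rng.standard_normal((5, 5)))[0] + 0.3 * rng.standard_normal((30, 5))
    _, _, disparity = scipy_procrustes(X, Y)
    res = procrustes_test(X, Y, n_perm=19, seed=0)
    assert res.m2 == pytest.approx(disparity, rel=1e-9)


def test_statistic_symmetric_and_p_respects_add_one_rule():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((50, 4))
    Y = rng.standard_normal((50, 4))
    a = procrustes_test(X, Y, n_perm=99, seed=5)
    b = procrustes_test(Y, X, n_perm=99, seed=5)
    assert a.m2 == pytest.approx(b.m2, rel=1e-9)
    assert a.p_value >= 1 / 100
    assert procrustes_test(X, X, n_perm=99, seed=5).p_value == pytest.approx(1 / 100)


def test_null_m2_is_large_and_p_nonextreme():
    rng = np.random.default_rng(13)
    X = rng.standard_normal((50, 4))
    Y = rng.standard_normal((50, 4))
    res = procrustes_test(X, Y, n_perm=199, seed=1)
    assert res.m2 > 0.5
    assert res.p_value > 0.01


def test_procrustes_input_validation():
    X = np.random.default_rng(0).standard_normal((2, 2))
    with pytest.raises(ValueError):
        procrustes_test(X, X)
    with pytest.raises(ValueError):
        procrustes_test(np.zeros((5, 2)), np.ones((4, 2)))


def test_nutrient_configuration_scales_columns():
    rng = np.random.default_rng(3)
    M = rng.standard_normal((20, 3)) * np.array([1.0, 100.0, 1e4])
    coords = nutrient_configuration(M)
    # embedding of z-scored data: total variance ~ number of columns
    assert coords.shape[0] == 20
    assert (coords**2).sum() == pytest.approx(3 * 19, rel=0.01)
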