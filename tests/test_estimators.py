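import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_table
from duomr.estimators import (
    _weighted_median_point,
    egger,
    exclude_and_rerun,
    ivw,
    mode_based,
    wald_ratios,
    weighted_median,
)
from duomr.summary_io import orient_positive


# ---------------------------------------------------------------------------
# wald_ratios


def test_wald_ratio_unit_exposure(make_table):
    t = make_table([1.0], [0.5], [0.1])
    (r,) = wald_ratios(t, exposure="hdl")
    assert r.ratio == 0.5
    assert r.se_ratio == 0.1
    assert r.weight == pytest.approx(100.0)


def test_wald_ratio_scaling(make_table):
    t = make_table([2.0], [0.5], [0.1])
    (r,) = wald_ratios(t, exposure="hdl")
    assert r.ratio == 0.25
    assert r.se_ratio == pytest.approx(0.05)


def test_wald_ratio_orientation_invariance(make_table):
    a = wald_ratios(make_table([1.5], [0.3], [0.1]), exposure="hdl")[0]
    b = wald_ratios(make_table([-1.5], [-0.3], [0.1]), exposure="hdl")[0]
    assert a.ratio == b.ratio
    assert a.se_ratio == b.se_ratio


def test_wald_ratio_zero_exposure_excluded(make_table):
    t = make_table([0.0, 1.0], [0.1, 0.5], [0.1, 0.1])
    ratios = wald_ratios(t, exposure="hdl")
    assert len(ratios) == 1
    assert ratios[0].snp_id == "rs1"


# ---------------------------------------------------------------------------
# ivw


def _wls_origin_oracle(x, y, w):
    """Independent zero-intercept WLS via lstsq on rescaled data."""
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq((sw * x)[:, None], sw * y, rcond=None)
    return float(coef[0])


def test_ivw_equal_ratios(make_table):
    t = make_table([1.0, 2.0], [0.5, 1.0], [0.1, 0.1])
    assert ivw(t).estimate == pytest.approx(0.5)


def test_ivw_weighted_least_squares_example(make_table):
    # frozen from the zero-intercept WLS oracle: slope = (1*1+2*1)/(1+4) = 0.6
    t = make_table([1.0, 2.0], [1.0, 1.0], [1.0, 1.0])
    est = ivw(t)
    assert est.estimate == pytest.approx(0.6)
    assert est.estimate == pytest.approx(
        _wls_origin_oracle(np.array([1.0, 2.0]), np.array([1.0, 1.0]),
                           np.ones(2))
    )


def test_ivw_single_snp_errors(make_table):
    t = make_table([1.0], [0.5], [0.1])
    with pytest.raises(ValueError, match="wald_ratios"):
        ivw(t)


def test_ivw_matches_oracle_on_random_tables(rng):
    for _ in range(100):
        n = int(rng.integers(2, 40))
        bzx = rng.normal(0, 0.2, n)
        bzx[bzx == 0] = 0.1
        bzy = rng.normal(0, 0.05, n)
        sezy = rng.uniform(0.005, 0.1, n)
        t = build_table(bzx, bzy, sezy)
        est = ivw(t)
        oracle = _wls_origin_oracle(bzx, bzy, 1.0 / sezy**2)
        assert abs(est.estimate - oracle) < 1e-12


def test_ivw_fixed_vs_random_effects(make_table):
    t = make_table([1.0, 2.0, 3.0], [0.5, 0.2, 1.4], [0.1, 0.1, 0.1])
    re = ivw(t, random_effects=True)
    fe = ivw(t, random_effects=False)
    assert re.estimate == fe.estimate
    assert re.se >= fe.se  # floor at 1 never shrinks the fixed SE


def test_ivw_random_effects_floor(make_table):
    # exact line through origin: sigma << 1, so RE must equal FE
    t = make_table([1.0, 2.0, 3.0], [0.5, 1.0, 1.5], [0.1, 0.1, 0.1])
    assert ivw(t).se == ivw(t, random_effects=False).se


# ---------------------------------------------------------------------------
# egger


def test_egger_exact_line(make_table):
    t = make_table([1.0, 2.0, 3.0], [0.3, 0.5, 0.7], [0.1, 0.1, 0.1],
                   oriented_to="hdl")
    est = egger(t)
    assert est.estimate == pytest.approx(0.2)
    assert est.intercept == pytest.approx(0.1)


def test_egger_line_through_origin_matches_ivw(make_table):
    t = make_table([1.0, 2.0, 3.0], [0.4, 0.8, 1.2], [0.1, 0.1, 0.1],
                   oriented_to="hdl")
    est = egger(t)
    assert est.intercept == pytest.approx(0.0, abs=1e-12)
    assert est.estimate == pytest.approx(ivw(t).estimate)


def test_egger_requires_orientation(make_table):
    t = make_table([1.0, 2.0, 3.0], [0.3, 0.5, 0.7], [0.1, 0.1, 0.1])
    with pytest.raises(ValueError, match="orient"):
        egger(t)


def test_egger_recovers_directional_pleiotropy(rng):
    n = 50
    bzx = rng.uniform(0.05, 0.3, n)
    truth, offset = 0.15, 0.02
    sezy = np.full(n, 0.005)
    bzy = truth * bzx + offset + rng.normal(0, sezy)
    t = build_table(bzx, bzy, sezy, oriented_to="hdl")
    est = egger(t)
    assert abs(est.intercept - offset) < 3 * est.intercept_se
    assert abs(est.estimate - truth) < 3 * est.se


def test_egger_needs_three(make_table):
    t = make_table([1.0, 2.0], [0.3, 0.5], [0.1, 0.1], oriented_to="hdl")
    with pytest.raises(ValueError, match=">= 3"):
        egger(t)


# ---------------------------------------------------------------------------
# weighted median


def test_weighted_median_simple(make_table):
    t = make_table([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [0.1, 0.1, 0.1])
    est = weighted_median(t, n_boot=200, seed=1)
    assert est.estimate == pytest.approx(2.0)


def test_weighted_median_interpolation_oracle(make_table):
    # ratios (1,2,3,10) with normalized weights (0.4,0.2,0.2,0.2):
    # cumulative midpoints (0.2, 0.5, 0.7, 0.9) -> p=0.5 hits ratio 2 exactly
    assert _weighted_median_point(
        np.array([1.0, 2.0, 3.0, 10.0]), np.array([0.4, 0.2, 0.2, 0.2])
    ) == pytest.approx(2.0)
    # realize the same weights through betas: w = bzx^2/sezy^2
    bzx = np.array([2.0, np.sqrt(2), np.sqrt(2), np.sqrt(2)])
    bzy = bzx * np.array([1.0, 2.0, 3.0, 10.0])
    t = make_table(bzx, bzy, np.ones(4))
    est = weighted_median(t, n_boot=200, seed=1)
    assert est.estimate == pytest.approx(2.0)


def test_weighted_median_within_ratio_range(rng):
    for _ in range(20):
        n = int(rng.integers(3, 20))
        bzx = rng.uniform(0.05, 0.5, n)
        bzy = rng.normal(0, 0.1, n)
        t = build_table(bzx, bzy, rng.uniform(0.01, 0.1, n))
        ratios = bzy / bzx
        est = weighted_median(t, n_boot=100, seed=3)
        assert ratios.min() - 1e-12 <= est.estimate <= ratios.max() + 1e-12


def _invalid_weight_table(rng, frac_invalid, n=30, truth=0.1, offset=0.3):
    """Equal-strength instruments; a fraction carries a pleiotropic offset."""
    bzx = rng.uniform(0.18, 0.22, n)
    sezy = np.full(n, 0.004)
    n_bad = int(round(frac_invalid * n))
    bzy = truth * bzx + rng.normal(0, sezy)
    bzy[:n_bad] += offset * bzx[:n_bad]  # proportional, keeps weights equalish
    return build_table(bzx, bzy, sezy), truth


def test_weighted_median_breakdown_point(rng):
    t40, truth = _invalid_weight_table(rng, 0.4)
    est40 = weighted_median(t40, n_boot=400, seed=11)
    assert abs(est40.estimate - truth) < 3 * est40.se

    t60, truth = _invalid_weight_table(rng, 0.6)
    est60 = weighted_median(t60, n_boot=400, seed=11)
    assert abs(est60.estimate - truth) > 3 * est60.se


def test_weighted_median_needs_three(make_table):
    t = make_table([1.0, 2.0], [0.3, 0.5], [0.1, 0.1])
    with pytest.raises(ValueError, match=">= 3"):
        weighted_median(t, n_boot=100, seed=0)


# ---------------------------------------------------------------------------
# mode-based


def test_mode_dominant_cluster(make_table):
    t = make_table([1.0, 1.0, 1.0, 1.0], [1.0, 1.001, 0.999, 5.0],
                   [0.1, 0.1, 0.1, 0.1])
    est = mode_based(t, n_boot=100, seed=2)
    ratios = np.array([1.0, 1.001, 0.999, 5.0])
    from duomr.estimators import _mode_bandwidth

    h = _mode_bandwidth(ratios, 1.0)
    assert abs(est.estimate - 1.0) < h


def test_mode_degenerate_all_equal(make_table):
    t = make_table([1.0, 2.0, 4.0], [0.3, 0.6, 1.2], [0.1, 0.1, 0.1])
    est = mode_based(t, n_boot=100, seed=2)
    assert est.estimate == pytest.approx(0.3)
    assert est.se > 0


def test_weighted_mode_zempa(rng):
    # valid cluster holds a plurality (45%) of weight but <50%; the rest is
    # split between two discordant pleiotropic clusters. The mode tracks the
    # valid cluster while IVW is pulled away.
    truth = 0.1
    n_valid, n_bad1, n_bad2 = 9, 6, 5
    bzx = rng.uniform(0.18, 0.22, n_valid + n_bad1 + n_bad2)
    sezy = np.full(len(bzx), 0.002)
    bzy = truth * bzx + rng.normal(0, sezy)
    bzy[n_valid:n_valid + n_bad1] += 0.4 * bzx[n_valid:n_valid + n_bad1]
    bzy[n_valid + n_bad1:] += 0.8 * bzx[n_valid + n_bad1:]
    t = build_table(bzx, bzy, sezy)
    # phi below 1 sharpens the kernel so nearby invalid clusters do not
    # drag the density maximum (bandwidth is an exposed tuning parameter)
    est = mode_based(t, weighted=True, phi=0.5, n_boot=400, seed=5)
    est_ivw = ivw(t)
    assert abs(est.estimate - truth) < 3 * est.se
    assert abs(est_ivw.estimate - truth) > 3 * est_ivw.se


# ---------------------------------------------------------------------------
# invariances across estimators


def _flip_rows(table, idx):
    df = table.df.copy()
    cols = [f"beta_{e}" for e in table.exposures] + ["beta_mat", "beta_fet"]
    df.loc[idx, cols] = -df.loc[idx, cols]
    from duomr.summary_io import InstrumentTable

    return InstrumentTable(df, table.exposures)


def test_sign_flip_invariance(rng):
    bzx = rng.uniform(0.1, 0.5, 12)
    bzy = rng.normal(0, 0.05, 12)
    sezy = rng.uniform(0.01, 0.05, 12)
    t = build_table(bzx, bzy, sezy)
    flipped = _flip_rows(t, [0, 3, 7])
    kw = dict(n_boot=200, seed=9)
    assert ivw(flipped).estimate == pytest.approx(ivw(t).estimate, abs=1e-14)
    assert weighted_median(flipped, **kw).estimate == pytest.approx(
        weighted_median(t, **kw).estimate, abs=1e-12)
    assert mode_based(flipped, **kw).estimate == pytest.approx(
        mode_based(t, **kw).estimate, abs=1e-9)
    # egger needs re-orientation first, after which the slope is unchanged
    e1 = egger(orient_positive(t, "hdl"))
    e2 = egger(orient_positive(flipped, "hdl"))
    assert e1.estimate == pytest.approx(e2.estimate, abs=1e-14)
    assert e1.intercept == pytest.approx(e2.intercept, abs=1e-14)


def test_scale_equivariance(rng):
    bzx = rng.uniform(0.1, 0.5, 10)
    bzy = rng.normal(0, 0.05, 10)
    sezy = rng.uniform(0.01, 0.05, 10)
    c = 3.7
    t1 = build_table(bzx, bzy, sezy, oriented_to="hdl")
    t2 = build_table(bzx, c * bzy, c * sezy, oriented_to="hdl")
    for fn in (ivw, egger):
        a, b = fn(t1), fn(t2)
        assert b.estimate == pytest.approx(c * a.estimate)
        assert b.se == pytest.approx(c * a.se)
    kw = dict(n_boot=200, seed=13)
    for fn in (weighted_median, lambda t, **k: mode_based(t, **k)):
        a, b = fn(t1, **kw), fn(t2, **kw)
        assert b.estimate == pytest.approx(c * a.estimate, rel=1e-6, abs=1e-9)
        assert b.se == pytest.approx(c * a.se, rel=0.05)


# ---------------------------------------------------------------------------
# exclude_and_rerun


def test_exclude_uninfluential_snp(make_table):
    # excluded SNP's ratio equals the ivw estimate of the others
    t = make_table([1.0, 2.0, 1.0, 3.0], [0.5, 1.0, 0.5, 1.5],
                   [0.1, 0.1, 0.1, 0.1])
    comps = exclude_and_rerun(t, ["rs2"], ["ivw"])
    assert comps[0].reduced.estimate == pytest.approx(comps[0].original.estimate)


def test_exclude_discordant_snp_exact(make_table):
    t = make_table([1.0, 1.0, 1.0, 1.0], [0.3, 0.3, 0.3, 2.0],
                   [0.1, 0.1, 0.1, 0.1])
    comps = exclude_and_rerun(t, ["rs3"], ["ivw"])
    assert comps[0].reduced.estimate == pytest.approx(0.3)


def test_exclude_influential_outlier_leave_one_out(rng, make_table):
    bzx = rng.uniform(0.2, 0.4, 10)
    sezy = np.full(10, 0.01)
    bzy = 0.1 * bzx + rng.normal(0, sezy)
    bzy[4] += 0.5  # influential outlier
    t = build_table(bzx, bzy, sezy)
    full = ivw(t).estimate
    deltas = {}
    for snp in t.snp_ids:
        comps = exclude_and_rerun(t, [snp], ["ivw"])
        deltas[snp] = abs(comps[0].reduced.estimate - full)
    assert max(deltas, key=deltas.get) == "rs4"


def test_exclude_missing_snp_errors(make_table):
    t = make_table([1.0, 2.0], [0.5, 1.0], [0.1, 0.1])
    with pytest.raises(ValueError, match="not in table"):
        exclude_and_rerun(t, ["rs99"], ["ivw"])


def test_exclude_below_minimum_skips(make_table):
    t = make_table([1.0, 2.0, 3.0], [0.5, 1.0, 1.5], [0.1, 0.1, 0.1],
                   oriented_to="hdl")
    comps = exclude_and_rerun(t, ["rs0"], ["ivw", "egger"])
    assert [c.method for c in comps] == ["ivw"]  # egger needs 3, skipped
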