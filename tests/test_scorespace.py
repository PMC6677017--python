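"""Score-space mapping: splines, Johnson S_U, naive-Bayes scores, C2."""

import numpy as np
import pytest
from scipy.integrate import quad

from solventscope.config import ALL_FEATURES
from solventscope.scorespace import (DecorrelationModel, JsuParams, Rpms,
                                     ScorePipelineParams, WaterScoreStats,
                                     c2_score, compute_scores, decorrelate,
                                     fit_rpms, jsu_pdf, raw_score,
                                     rescale_score)

# --- RPMS -------------------------------------------------------------------

def test_rpms_constant_data():
    r = np.linspace(1, 4, 25)
    sp = fit_rpms(r, np.full(25, 2.5))
    for x in (0.8, 1.0, 2.3, 4.0, 5.5):
        assert sp(x) == pytest.approx(2.5, abs=1e-9)


def test_rpms_exact_interpolation_at_six_points():
    r = np.array([1.0, 1.4, 2.0, 2.7, 3.3, 4.0])
    y = np.array([0.3, 1.1, -0.4, 2.2, 0.9, 1.5])
    sp = fit_rpms(r, y)
    assert max(abs(sp(a) - b) for a, b in zip(r, y)) < 1e-9


def test_rpms_reproduces_linear_trend():
    r = np.linspace(1, 4, 40)
    sp = fit_rpms(r, 2 * r - 1)
    xs = np.linspace(1, 4, 200)
    assert np.max(np.abs(sp(xs) - (2 * xs - 1))) < 1e-6


def test_rpms_clamps_outside_range():
    r = np.linspace(1, 4, 40)
    sp = fit_rpms(r, 2 * r - 1)
    assert sp(0.2) == pytest.approx(sp(1.0))
    assert sp(9.0) == pytest.approx(sp(4.0))


def test_rpms_serialization_roundtrip():
    sp = fit_rpms(np.linspace(1, 4, 12), np.sin(np.linspace(1, 4, 12)))
    back = Rpms.from_dict(sp.to_dict())
    xs = np.linspace(0.5, 5, 50)
    assert np.array_equal(sp(xs), back(xs))


# --- Johnson S_U ------------------------------------------------------------

def test_jsu_standard_normal_value():
    p = JsuParams(gamma=0, delta=1, xi=0, lam=1)
    # at gamma=0, delta=1, x=0: (1/sqrt(2*pi)) * 1 * exp(0) = 0.39894...
    assert jsu_pdf(0.0, p) == pytest.approx(1 / np.sqrt(2 * np.pi), abs=1e-12)


def test_jsu_symmetry_when_gamma_zero():
    p = JsuParams(gamma=0, delta=1.7, xi=0.4, lam=2.0)
    for a in (0.3, 1.1, 2.7):
        assert jsu_pdf(p.xi + a, p) == pytest.approx(jsu_pdf(p.xi - a, p), abs=1e-12)


@pytest.mark.parametrize("params", [
    (0.5, 1.2, 0.0, 1.0), (-1.0, 1.1, 2.0, 0.5), (2.0, 2.5, -1.0, 3.0)])
def test_jsu_integrates_to_one(params):
    p = JsuParams(*params)
    # integrate over the image of z in [-12, 12] under x = xi + lam*sinh((z-g)/d)
    lo = p.xi + p.lam * np.sinh((-12 - p.gamma) / p.delta)
    hi = p.xi + p.lam * np.sinh((12 - p.gamma) / p.delta)
    val, _ = quad(lambda x: jsu_pdf(x, p), lo, hi, limit=500,
                  points=[p.xi - p.lam, p.xi, p.xi + p.lam])
    assert val == pytest.approx(1.0, abs=1e-4)


def test_jsu_pdf_matches_scipy():
    from scipy.stats import johnsonsu
    p = JsuParams(gamma=-0.7, delta=1.6, xi=0.3, lam=2.1)
    xs = np.linspace(-8, 8, 81)
    ours = jsu_pdf(xs, p)
    ref = johnsonsu.pdf(xs, p.gamma, p.delta, loc=p.xi, scale=p.lam)
    assert np.allclose(ours, ref, atol=1e-12)


def test_jsu_analytic_moments_match_samples():
    p = JsuParams(gamma=0.8, delta=1.5, xi=1.0, lam=2.0)
    rng = np.random.default_rng(0)
    x = p.xi + p.lam * np.sinh((rng.standard_normal(200_000) - p.gamma) / p.delta)
    assert x.mean() == pytest.approx(p.mean(), abs=0.02)
    assert x.var() == pytest.approx(p.var(), rel=0.02)


def test_jsu_invalid_params_rejected():
    with pytest.raises(ValueError):
        JsuParams(gamma=0, delta=-1, xi=0, lam=1)


# --- raw score --------------------------------------------------------------

def _pdf_with_value_at_zero(v):
    """JSU whose density at x=0 is exactly v (pure scale family)."""
    return JsuParams(gamma=0, delta=1, xi=0, lam=1 / (v * np.sqrt(2 * np.pi)))


def test_raw_score_worked_likelihood_example():
    """pdf values 0.2 (sulfate) and 0.05 (water) -> likelihood ratio 4, ln 4."""
    ps, pw = _pdf_with_value_at_zero(0.2), _pdf_with_value_at_zero(0.05)
    assert jsu_pdf(0.0, ps) == pytest.approx(0.2, abs=1e-12)
    assert jsu_pdf(0.0, pw) == pytest.approx(0.05, abs=1e-12)
    contribution = raw_score([0.0], [ps], [pw])
    assert contribution == pytest.approx(np.log(4.0), abs=1e-12)


def test_raw_score_zero_when_pdfs_equal():
    p = JsuParams(gamma=0.3, delta=1.4, xi=0.2, lam=1.1)
    vals = np.array([0.1, -0.5, 2.0])
    assert raw_score(vals, [p] * 3, [p] * 3) == pytest.approx(0.0, abs=1e-12)


def test_raw_score_matches_termwise_oracle():
    rng = np.random.default_rng(4)
    ps = [JsuParams(*t) for t in rng.uniform([-1, 0.5, -1, 0.5], [1, 2, 1, 2], (5, 4))]
    pw = [JsuParams(*t) for t in rng.uniform([-1, 0.5, -1, 0.5], [1, 2, 1, 2], (5, 4))]
    for _ in range(200):
        v = rng.normal(size=5)
        expected = sum(np.log(max(jsu_pdf(x, a), 1e-12)) - np.log(max(jsu_pdf(x, b), 1e-12))
                       for x, a, b in zip(v, ps, pw))
        assert raw_score(v, ps, pw) == pytest.approx(expected, abs=1e-12)


def test_raw_score_negates_when_classes_swapped():
    rng = np.random.default_rng(5)
    ps = [JsuParams(0.5, 1.2, 0.3, 1.0)] * 4
    pw = [JsuParams(-0.2, 1.8, -0.1, 0.7)] * 4
    v = rng.normal(size=4)
    assert raw_score(v, ps, pw) == pytest.approx(-raw_score(v, pw, ps), abs=1e-12)


# --- rescale / C2 -----------------------------------------------------------

def test_rescale_monotone_and_midpoint_zero():
    pair = (Rpms.constant(3.0), Rpms.constant(2.0))
    assert rescale_score(3.0, 2.0, pair) == pytest.approx(0.0)
    xs = np.linspace(-5, 5, 50)
    ys = rescale_score(xs, np.full(50, 2.0), pair)
    assert np.all(np.diff(ys) > 0)


def test_c2_closed_forms():
    w = WaterScoreStats(mu_ed=-1.0, sd_ed=0.5, mu_cc=-2.0, sd_cc=1.0)
    c2, p = c2_score(-1.0, -2.0, w)
    assert c2 == pytest.approx(0.0) and p == pytest.approx(0.0)
    c2, p = c2_score(-0.5, -2.0, w)   # one water-sd above the ED mean
    assert c2 == pytest.approx(1.0)
    assert p == pytest.approx(1 - np.exp(-0.5), abs=1e-12)


def test_p_notwater_monotone_in_c2():
    w = WaterScoreStats(0, 1, 0, 1)
    eds = np.linspace(0, 4, 20)
    _, ps = c2_score(eds, np.zeros(20), w)
    assert np.all(np.diff(ps) >= 0)


# --- composed pipeline ------------------------------------------------------

def _identity_params():
    """Pipeline params that pass values through unchanged (for contracts)."""
    const = Rpms.constant
    eye = DecorrelationModel(splines=[[const(1.0 if i == j else 0.0)
                                       for j in range(19)] for i in range(19)])
    std_jsu = JsuParams(0, 1, 0, 1)
    sep_jsu = {"sulfate": [const(0.0), const(1.0), const(1.0), const(1.0)],
               "water": [const(0.0), const(1.0), const(-1.0), const(1.0)]}
    return ScorePipelineParams(
        ed_standardize=[(const(0.0), const(1.0))] * 19,
        decorrelation=eye,
        ed_scale=[(const(0.0), const(1.0))] * 19,
        ed_jsu=[sep_jsu] * 19,
        ed_rescale=(const(0.0), const(1.0)),
        cc_standardize=[(0.0, 1.0)] * 2,
        cc_jsu=[{"sulfate": JsuParams(0, 1, 1, 1), "water": JsuParams(0, 1, -1, 1)}] * 2,
        cc_rescale=(const(0.0), const(1.0)),
    )


def test_parameter_census_counts():
    census = _identity_params().census()
    assert census == {"ed_total": 591, "ed_decorrelation": 361,
                      "cc_rimps": 20, "cc_rpms": 2}


def test_identity_decorrelation_passthrough():
    params = _identity_params()
    rng = np.random.default_rng(2)
    Z = rng.normal(size=(50, 19))
    Y = decorrelate(Z, np.full(50, 2.0), params.decorrelation)
    assert np.allclose(Y, Z, atol=1e-12)


def test_compute_scores_sign_convention_and_key_access():
    params = _identity_params()
    w = WaterScoreStats(mu_ed=-5.0, sd_ed=2.0, mu_cc=-1.0, sd_cc=1.0)
    sulfate_like = {f: 1.0 for f in ALL_FEATURES}
    water_like = {f: -1.0 for f in ALL_FEATURES}
    s_pos = compute_scores(sulfate_like, 2.0, params, w)
    s_neg = compute_scores(water_like, 2.0, params, w)
    assert s_pos.ed > 0 and s_pos.cc > 0
    assert s_neg.ed < 0 and s_neg.cc < 0
    # keyed access: input dict ordering is irrelevant
    shuffled = dict(reversed(list(sulfate_like.items())))
    s2 = compute_scores(shuffled, 2.0, params, w)
    assert (s2.ed, s2.cc, s2.c2) == (s_pos.ed, s_pos.cc, s_pos.c2)


def test_compute_scores_missing_feature_named():
    params = _identity_params()
    w = WaterScoreStats(0, 1, 0, 1)
    vals = {f: 0.0 for f in ALL_FEATURES if f != "CC7"}
    with pytest.raises(ValueError, match="CC7"):
        compute_scores(vals, 2.0, params, w)


def test_end_to_end_determinism():
    params = _identity_params()
    w = WaterScoreStats(0, 1, 0, 1)
    vals = {f: 0.37 for f in ALL_FEATURES}
    a = compute_scores(vals, 2.1, params, w)
    b = compute_scores(vals, 2.1, params, w)
    assert (a.ed, a.cc, a.c2, a.p_notwater) == (b.ed, b.cc, b.c2, b.p_notwater)
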