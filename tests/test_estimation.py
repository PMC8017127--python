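"""Tests of parameter spaces, the MML fitter and the two-step driver."""

import numpy as np
import pytest

from timeirt import (
    Dataset,
    FitOptions,
    ItemTimeParams,
    LatentSpec,
    MissingAnchorError,
    ModelSpec,
    QuadratureSpec,
    build_parameter_space,
    fit,
    marginal_loglik,
    two_step_analysis,
)
from timeirt.estimation import (
    COUNTRY_LEVELS,
    _loglik_and_grad,
    _safe_loglik,
    starting_values,
)
from timeirt.synthetic_data import ScenarioConfig, generate, paper_like_scenario

QUAD = QuadratureSpec(11)
FAST = FitOptions(compute_se=False)


def _free_symbols(space):
    return {e.symbol for e in space.free_entries}


def _fixed(space, symbol):
    return {e.key: e.value for e in space.entries if not e.free and e.symbol == symbol}


class TestParameterSpaces:
    def test_m1_international(self, toy_items):
        sp = build_parameter_space("M1", "international", n_cats=(2, 3, 2))
        assert _free_symbols(sp) == {"a", "b"}
        assert sp.n_free == 3 + 4  # 3 discriminations, 1+2+1 thresholds
        lat_fixed = {e.symbol: e.value for e in sp.entries
                     if not e.free and e.symbol.startswith(("mu", "var", "rho"))}
        assert lat_fixed["mu_theta"] == 0 and lat_fixed["var_theta"] == 1

    def test_m2_international_anchoring(self, toy_items):
        m1 = ModelSpec("M1", toy_items)
        sp = build_parameter_space("M2", "international", {"M1_international": m1})
        assert _free_symbols(sp) == {"xi", "lam", "sig2", "mu_theta", "var_theta", "rho"}
        fixed_a = _fixed(sp, "a")
        assert fixed_a[("a", 0, None)] == toy_items[0].discrimination
        fixed_lat = {e.symbol: e.value for e in sp.entries
                     if not e.free and e.symbol in ("mu_tau", "var_tau")}
        assert fixed_lat == {"mu_tau": 0, "var_tau": 1}

    def test_m3_international_fixes_rho(self, toy_items):
        sp = build_parameter_space("M3", "international",
                                   {"M1_international": ModelSpec("M1", toy_items)})
        assert "phi" in _free_symbols(sp)
        assert _fixed(sp, "rho")[("rho", None, None)] == 0

    def test_m2_full_frees_latents_only(self, toy_m2, toy_items):
        anchors = {"M1_international": ModelSpec("M1", toy_items),
                   "M2_international": toy_m2}
        sp = build_parameter_space("M2", "Full", anchors)
        assert _free_symbols(sp) == {"mu_theta", "var_theta", "mu_tau", "var_tau", "rho"}
        assert sp.n_free == 5
        assert _fixed(sp, "xi")[("xi", 0, None)] == toy_m2.item_time[0].intensity

    def test_ladder_frees_nested_supersets(self, toy_m2, toy_items):
        anchors = {"M1_international": ModelSpec("M1", toy_items),
                   "M2_international": toy_m2}
        frees = [_free_symbols(build_parameter_space("M2", lev, anchors))
                 for lev in COUNTRY_LEVELS]
        time_syms = [f & {"xi", "lam", "sig2"} for f in frees]
        assert time_syms == [set(), {"sig2"}, {"sig2", "xi"}, {"sig2", "xi", "lam"}]
        # Weak and Struct fix the speed mean for identification
        weak = build_parameter_space("M2", "Weak", anchors)
        assert _fixed(weak, "mu_tau")[("mu_tau", None, None)] == 0

    def test_m3_struct_anchors_proficiency_variance(self, toy_m3, toy_items):
        anchors = {"M1_international": ModelSpec("M1", toy_items),
                   "M3_international": toy_m3,
                   "M1_Full": ModelSpec("M1", toy_items, None, LatentSpec(0.2, 1.37))}
        sp = build_parameter_space("M3", "Struct", anchors)
        assert _free_symbols(sp) == {"mu_theta", "xi", "lam", "sig2", "phi"}
        assert _fixed(sp, "var_theta")[("var_theta", None, None)] == 1.37
        assert _fixed(sp, "rho")[("rho", None, None)] == 0
        assert _fixed(sp, "var_tau")[("var_tau", None, None)] == 1

    def test_missing_anchor_named(self, toy_items):
        with pytest.raises(MissingAnchorError, match="M2_international"):
            build_parameter_space("M2", "Full",
                                  {"M1_international": ModelSpec("M1", toy_items)})
        with pytest.raises(MissingAnchorError, match="M1_international"):
            build_parameter_space("M2", "international", {})


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, toy_data, toy_items):
        rng = np.random.default_rng(7)
        anchors = {"M1_international": ModelSpec("M1", toy_items)}
        for model_id in ("M2", "M3"):
            sp = build_parameter_space(model_id, "international", anchors)
            x = starting_values(toy_data, sp)
            x += 0.05 * rng.standard_normal(x.shape)
            for j, e in enumerate(sp.free_entries):
                if e.symbol in ("sig2", "var_theta"):
                    x[j] = abs(x[j]) + 0.2
            _, g = _loglik_and_grad(toy_data, sp, QUAD, x)
            for j in range(len(g)):
                h = 1e-6 * (1 + abs(x[j]))
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                fd = (_safe_loglik(toy_data, sp, QUAD, xp)
                      - _safe_loglik(toy_data, sp, QUAD, xm)) / (2 * h)
                assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-6), sp.free_entries[j]


@pytest.fixture(scope="module")
def m2_sim():
    """One moderate M2 dataset with known truth (single group)."""
    base = paper_like_scenario(n_groups=1, persons_per_group=800, rho=0.4, seed=5)
    cfg = ScenarioConfig(
        n_groups=1, persons_per_group=800, item_acc=base.item_acc,
        item_time=base.item_time, generating_model="M2",
        latent=(LatentSpec(corr=0.4),), miss_rates=base.miss_rates, seed=5)
    return generate(cfg)


class TestFit:
    def test_all_fixed_returns_loglik_only(self, toy_data, toy_m2, toy_items):
        anchors = {"M1_international": ModelSpec("M1", toy_items),
                   "M2_international": toy_m2}
        sp = build_parameter_space("M2", "Full", anchors)
        sp_fixed = type(sp)(sp.model_id,
                            tuple(type(e)(e.symbol, e.item, e.cat, False,
                                          e.value if not e.free else 0.5)
                                  for e in sp.entries),
                            sp.n_cats, sp.level)
        fr = fit(toy_data, sp_fixed, QUAD)
        assert fr.n_free == 0 and fr.converged
        assert fr.loglik == pytest.approx(
            marginal_loglik(toy_data, sp_fixed.to_spec(), QUAD))

    def test_fit_improves_on_start(self, m2_sim):
        data, truth = m2_sim
        sp = build_parameter_space("M1", "international", n_cats=(2, 3, 3, 3, 2, 2, 2, 2, 2, 2))
        x0 = starting_values(data, sp)
        fr = fit(data, sp, QUAD, FAST)
        assert fr.converged
        assert fr.loglik >= _safe_loglik(data, sp, QUAD, x0)

    def test_moderate_recovery_and_se(self, m2_sim):
        """Time parameters and rho recovered on one n=800 draw; SEs finite."""
        data, truth = m2_sim
        sp1 = build_parameter_space("M1", "international",
                                    n_cats=tuple(i.n_categories for i in truth.specs[0].item_acc))
        f1 = fit(data, sp1, QUAD, FAST)
        sp2 = build_parameter_space("M2", "international", {"M1_international": f1})
        f2 = fit(data, sp2, QUAD)
        assert f2.converged and f2.se_available
        true = truth.specs[0]
        est_lam = [it.speed_loading for it in f2.estimates.item_time]
        true_lam = [it.speed_loading for it in true.item_time]
        np.testing.assert_allclose(est_lam, true_lam, atol=0.1)
        assert f2.estimates.latent.corr == pytest.approx(0.4, abs=0.12)
        # carry-over: accuracy parameters equal the M1 estimates exactly
        for a_fit, a_m1 in zip(f2.estimates.item_acc, f1.estimates.item_acc):
            assert a_fit.discrimination == a_m1.discrimination
            assert a_fit.thresholds == a_m1.thresholds
        ses = np.array(list(f2.standard_errors.values()))
        assert np.all(ses > 0) and np.all(ses < 1)


@pytest.fixture(scope="module")
def small_two_step():
    cfg = paper_like_scenario(n_groups=2, persons_per_group=150, seed=9)
    data, truth = generate(cfg)
    res = two_step_analysis(data, QuadratureSpec(9), FitOptions(compute_se=False, maxiter=300))
    return data, truth, res


class TestTwoStep:
    def test_result_enumeration(self, small_two_step):
        data, truth, res = small_two_step
        groups = data.groups()
        # 3 international + per group: M1_Full + 4 M2 + 4 M3
        assert len(res.fits) == 3 + len(groups) * 9
        for g in groups:
            for lev in COUNTRY_LEVELS:
                assert ("M2", lev, g) in res.fits
                assert ("M3", lev, g) in res.fits

    def test_carry_over_exact(self, small_two_step):
        _, _, res = small_two_step
        m1 = res.international("M1").estimates
        for (model, level, group), fr in res.fits.items():
            if model == "M1" and level == "international":
                continue
            for a_fit, a_m1 in zip(fr.estimates.item_acc, m1.item_acc):
                assert a_fit.discrimination == a_m1.discrimination
                assert a_fit.thresholds == a_m1.thresholds

    def test_nesting_of_loglik(self, small_two_step):
        """Each ladder level frees a superset, so loglik is monotone
        (M3_Struct re-anchors the variance and is excluded)."""
        data, _, res = small_two_step
        tol = 0.05  # optimizer tolerance slack
        for g in data.groups():
            lls = [res.fits[("M2", lev, g)].loglik for lev in COUNTRY_LEVELS]
            assert lls[1] >= lls[0] - tol
            assert lls[2] >= lls[1] - tol
            assert lls[3] >= lls[2] - tol
            lls3 = [res.fits[("M3", lev, g)].loglik for lev in COUNTRY_LEVELS[:3]]
            assert lls3[1] >= lls3[0] - tol
            assert lls3[2] >= lls3[1] - tol

    def test_single_group_rejected(self, toy_data):
        single = Dataset(toy_data.responses, toy_data.times,
                         np.array(["A"] * toy_data.n_persons))
        with pytest.raises(ValueError, match="two groups"):
            two_step_analysis(single)

    def test_determinism(self):
        cfg = paper_like_scenario(n_groups=2, persons_per_group=60, seed=4)
        data, _ = generate(cfg)
        quad, opts = QuadratureSpec(7), FitOptions(compute_se=False)
        r1 = two_step_analysis(data, quad, opts, models=("M1", "M2"))
        r2 = two_step_analysis(data, quad, opts, models=("M1", "M2"))
        t1, t2 = r1.table(), r2.table()
        assert t1.equals(t2)
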