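"""Stochastic pasture-kangaroo-pig rangeland model."""

import numpy as np
import pytest

from ecotrap.dispersal import DispersalParams
from ecotrap.rangeland import (
    FixedMortalityControl,
    InteractiveState,
    NoControl,
    RainfallModel,
    RangelandParams,
    interactive_step,
    numerical_response,
    pasture_growth,
    replicate_interactive,
    run_interactive,
    run_shadow_twin,
    sample_quarterly_rainfall,
    total_offtake,
)

WEAK = DispersalParams(gamma=0.1)
STRONG = DispersalParams(gamma=1.0)


class TestRainfall:
    def test_moments_match_record(self):
        # resampling the negative tail of N(193, 90) shifts the mean up
        # ~3.6 mm and shrinks the SD a little; the draws must stay close
        # to the recorded quarterly moments
        rng = np.random.default_rng(7)
        draws = sample_quarterly_rainfall(RainfallModel(), rng, 100_000)
        assert draws.mean() == pytest.approx(193.0, abs=5.0)
        assert draws.std() == pytest.approx(90.0, abs=5.0)

    def test_never_negative(self):
        rng = np.random.default_rng(8)
        draws = sample_quarterly_rainfall(RainfallModel(), rng, 100_000)
        assert (draws >= 0).all()

    def test_scalar_draw(self):
        rng = np.random.default_rng(9)
        r = sample_quarterly_rainfall(RainfallModel(), rng)
        assert isinstance(r, float) and r >= 0

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            RainfallModel(family="gamma")


class TestPastureGrowth:
    def test_hand_value_at_initial_state(self):
        # independent arithmetic of the quarterly growth polynomial
        want = -55.12 - 0.01535 * 295 - 0.00056 * 295**2 + 0.69 * 193
        assert pasture_growth(295.0, 193.0) == pytest.approx(want, rel=1e-12)

    def test_increasing_in_rainfall(self):
        lo = pasture_growth(295.0, 100.0)
        hi = pasture_growth(295.0, 300.0)
        assert hi > lo

    def test_self_limiting_in_biomass(self):
        v = np.linspace(0, 1500, 200)
        dv = pasture_growth(v, 193.0)
        assert dv[-1] < 0  # heavy standing crop declines
        assert np.all(np.diff(dv) < 0)  # monotone decreasing in V


class TestOfftake:
    def test_no_herbivores_no_offtake(self):
        assert total_offtake(0.0, 0.0, 300.0) == 0.0

    def test_nothing_to_eat(self):
        assert total_offtake(45.0, 4.0, 0.0) == 0.0

    def test_additive_functional_responses(self):
        both = total_offtake(45.0, 4.0, 250.0)
        only_k = total_offtake(45.0, 0.0, 250.0)
        only_p = total_offtake(0.0, 4.0, 250.0)
        assert both == pytest.approx(only_k + only_p, rel=1e-12)

    def test_saturating_in_biomass(self):
        v = np.array([50.0, 200.0, 800.0, 5000.0])
        off = total_offtake(45.0, 4.0, v)
        assert np.all(np.diff(off) > 0)
        # near-saturated intake at high biomass
        assert off[-1] < off[-2] * 1.05


class TestNumericalResponse:
    @pytest.mark.parametrize("species", ["kangaroo", "pig"])
    def test_monotone_saturating(self, species):
        v = np.linspace(0, 2000, 500)
        r = numerical_response(species, v)
        assert np.all(np.diff(r) >= 0)
        assert r[-1] < np.inf

    def test_intercept_is_maximum_decline(self):
        assert numerical_response("kangaroo", 0.0) == pytest.approx(-1.6)
        assert numerical_response("pig", 0.0) == pytest.approx(-2.5)

    def test_pig_saturates_at_intrinsic_rate(self):
        # the satiated pig rate of increase is the species' r_m
        assert numerical_response("pig", 1e9) == pytest.approx(0.792, abs=1e-9)

    def test_unknown_species(self):
        with pytest.raises(ValueError):
            numerical_response("emu", 100.0)


@pytest.fixture
def params():
    return RangelandParams(prop_controlled=0.5, horizon_months=120)


class TestInteractiveStep:
    def test_dispersal_conserves_pigs(self, params):
        """Total pigs after a step is independent of gamma: dispersal
        only moves animals, it never creates or destroys them."""
        state = InteractiveState.initial(params, n=1)
        state.Pc[:] = 500.0  # asymmetric so the gradient is non-zero
        totals = []
        for disp in (WEAK, STRONG):
            nxt = interactive_step(state, 193.0, NoControl(), disp, params)
            totals.append(float(nxt.total_pigs()[0]))
        assert totals[0] == pytest.approx(totals[1], rel=1e-12)

    def test_state_stays_nonnegative(self, params):
        state = InteractiveState.initial(params, n=1)
        for _ in range(60):
            state = interactive_step(state, 0.0, FixedMortalityControl(0.9),
                                     STRONG, params)
        for name in ("Vc", "Vu", "Kc", "Ku", "Pc", "Pu", "Mc", "Mu"):
            assert np.all(getattr(state, name) >= 0.0), name

    def test_symmetry_without_control(self, params):
        """With no control, both patches see identical rainfall and start
        at equal density, so their densities stay equal every month."""
        res = run_interactive(params, NoControl(), STRONG, seed=3)
        dens_c = res.Pc / params.area_c
        dens_u = res.Pu / params.area_u
        assert np.allclose(dens_c, dens_u, rtol=1e-10)


class TestShadowTwin:
    def test_initial_counts_proportional_to_area(self, params):
        rain = np.full(41, 193.0)
        mc, mu = run_shadow_twin(params, rain)
        assert mc[0] == pytest.approx(4.0 * 0.5 * 1000.0)
        assert mu[0] == pytest.approx(4.0 * 0.5 * 1000.0)

    def test_main_run_equals_twin_when_control_off(self, params):
        """With control off and zero gradient the main run IS its twin."""
        res = run_interactive(params, NoControl(), WEAK, seed=11)
        assert np.allclose(res.Pc, res.Mc, rtol=1e-10)
        assert np.allclose(res.Pu, res.Mu, rtol=1e-10)

    def test_deterministic_given_rainfall(self, params):
        rng = np.random.default_rng(5)
        rain = sample_quarterly_rainfall(params.rainfall, rng, 41)
        a = run_shadow_twin(params, rain)
        b = run_shadow_twin(params, rain)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestReplicates:
    def test_seeded_reproducibility(self, params):
        kw = dict(n_reps=8, base_seed=42)
        a = replicate_interactive(params, FixedMortalityControl(0.9), STRONG, **kw)
        b = replicate_interactive(params, FixedMortalityControl(0.9), STRONG, **kw)
        assert a.mean_Pc == b.mean_Pc
        assert a.n_extinct == b.n_extinct
        assert np.array_equal(a.extinction_years, b.extinction_years)

    def test_replicates_independent_of_batch_size(self, params):
        """Replicate i is driven by child seed i, so the first replicates
        of a larger batch match a smaller batch exactly."""
        small = replicate_interactive(params, FixedMortalityControl(0.9),
                                      STRONG, n_reps=4, base_seed=1)
        large = replicate_interactive(params, FixedMortalityControl(0.9),
                                      STRONG, n_reps=8, base_seed=1)
        assert np.array_equal(small.per_rep_mean_Pc, large.per_rep_mean_Pc[:4])

    def test_heavy_control_drives_extinction(self, params):
        p = RangelandParams(prop_controlled=0.9)
        s = replicate_interactive(p, FixedMortalityControl(0.9), STRONG,
                                  n_reps=20, base_seed=2)
        assert s.n_extinct == 20
        assert s.mean_ext_years < 15

    def test_no_control_keeps_quasi_equilibrium(self):
        """Without control, 50-year pig density fluctuates around the
        rangeland quasi-equilibrium (a few pigs per km^2) and nothing
        goes extinct."""
        p = RangelandParams(prop_controlled=0.5)
        s = replicate_interactive(p, NoControl(), WEAK, n_reps=100,
                                  base_seed=10)
        assert s.n_extinct == 0
        mean_density = (s.mean_Pc + s.mean_Pu) / p.area_total_km2
        assert 1.0 < mean_density < 16.0  # around the initial 4 km^-2
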