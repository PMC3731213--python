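"""Occupancy model: configuration enumeration, closed forms, DP equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoccupancy.motifs import PWM
from thermoccupancy.stap_core import (
    BindingModel,
    enumerate_configurations,
    occupancy_brute_force,
    occupancy_dp,
    predict_window,
    site_weight,
)

from conftest import make_site, random_sites


@pytest.fixture
def primary_pwm() -> PWM:
    probs = np.full((6, 4), 0.01 / 3)
    probs[:, 0] = 0.99
    return PWM("M1", probs)


@pytest.fixture
def secondary_pwm() -> PWM:
    probs = np.full((6, 4), 0.01 / 3)
    probs[:, 1] = 0.99
    return PWM("M2", probs)


def single_model(gamma: float, pwm: PWM | None = None) -> BindingModel:
    pwm = pwm or PWM("M1", np.full((6, 4), 0.25), pseudocount=0.0)
    return BindingModel([pwm], [gamma])


class TestSiteWeight:
    def test_consensus_site_half_occupied_at_unit_gamma(self):
        site = make_site("M1", 0, 6, 1.0)
        q = site_weight(site, 1.0)
        assert q == 1.0
        assert q / (1 + q) == pytest.approx(0.5)

    def test_weight_scales_with_relative_affinity(self):
        assert site_weight(make_site("M1", 0, 6, 0.5), 1.0) == pytest.approx(0.5)

    def test_vanishing_gamma_means_no_binding(self):
        assert site_weight(make_site("M1", 0, 6, 1.0), 1e-12) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            site_weight(make_site("M1", 0, 6, 1.0), 0.0)


class TestEnumeration:
    def test_two_nonoverlapping_sites_give_four_configurations(self):
        sites = [make_site("M1", 0, 6, 0.9), make_site("M1", 20, 6, 0.5)]
        configs = enumerate_configurations(sites, single_model(1.0))
        assert len(configs) == 4
        weights = sorted(c.weight for c in configs)
        assert weights == pytest.approx(sorted([1.0, 0.9, 0.5, 0.45]))

    def test_overlapping_sites_exclude_joint_binding(self):
        sites = [make_site("M1", 0, 6, 0.9), make_site("M1", 3, 6, 0.5)]
        configs = enumerate_configurations(sites, single_model(1.0))
        assert len(configs) == 3

    def test_no_sites_leaves_the_empty_configuration(self):
        configs = enumerate_configurations([], single_model(1.0))
        assert len(configs) == 1
        assert configs[0].weight == 1.0
        assert occupancy_brute_force([], single_model(1.0)) == 0.0

    def test_too_many_sites_directs_to_dp(self):
        sites = [make_site("M1", 20 * i, 6, 0.5) for i in range(26)]
        with pytest.raises(ValueError, match="occupancy_dp"):
            enumerate_configurations(sites, single_model(1.0))


class TestWorkedExample:
    """The two-site example: q_A=0.9, q_B=0.5, then both weights doubled."""

    def test_baseline_occupancy(self):
        sites = [make_site("M1", 0, 6, 0.9), make_site("M1", 20, 6, 0.5)]
        occ = occupancy_brute_force(sites, single_model(1.0))
        assert occ == pytest.approx(2.3 / 2.85)
        assert round(occ, 3) == 0.807

    def test_doubled_concentration(self):
        sites = [make_site("M1", 0, 6, 0.9), make_site("M1", 20, 6, 0.5)]
        occ = occupancy_brute_force(sites, single_model(2.0))
        assert occ == pytest.approx(6.4 / 5.6)
        assert round(occ, 3) == 1.143

    def test_doubling_gamma_does_not_double_occupancy(self):
        sites = [make_site("M1", 0, 6, 0.9), make_site("M1", 20, 6, 0.5)]
        occ1 = occupancy_brute_force(sites, single_model(1.0))
        occ2 = occupancy_brute_force(sites, single_model(2.0))
        assert occ2 < 2 * occ1


class TestInteractionClosedForm:
    def _pair_model(self, omega, mode, d_T=150):
        return BindingModel(
            [
                PWM("M1", np.full((6, 4), 0.25), pseudocount=0.0),
                PWM("M2", np.full((6, 4), 0.25), pseudocount=0.0),
            ],
            [1.0, 1.0],
            omega=omega,
            d_T=d_T,
            mode=mode,
        )

    def test_cooperative_pair_matches_four_config_formula(self):
        sites = [make_site("M1", 0, 6, 1.0), make_site("M2", 20, 6, 1.0)]
        occ = occupancy_dp(sites, self._pair_model(4.0, "cooperative"))
        assert occ == pytest.approx(5.0 / 7.0)
        assert occupancy_brute_force(sites, self._pair_model(4.0, "cooperative")) == pytest.approx(occ)

    @pytest.mark.parametrize("q,r", [(1.0, 1.0), (0.3, 2.0), (5.0, 0.2)])
    def test_occupancy_monotone_in_omega(self, q, r):
        sites = [make_site("M1", 0, 6, q), make_site("M2", 20, 6, r)]
        neutral = occupancy_dp(sites, self._pair_model(1.0, "competition"))
        coop = occupancy_dp(sites, self._pair_model(5.0, "cooperative"))
        antag = occupancy_dp(sites, self._pair_model(0.2, "antagonistic"))
        assert antag < neutral < coop

    def test_out_of_range_pair_ignores_omega(self):
        sites = [make_site("M1", 0, 6, 1.0), make_site("M2", 200, 6, 1.0)]
        coop = occupancy_dp(sites, self._pair_model(5.0, "cooperative", d_T=30))
        neutral = occupancy_dp(sites, self._pair_model(1.0, "competition", d_T=30))
        assert coop == pytest.approx(neutral, rel=1e-12)

    def test_overlapping_competitor_lowers_primary_occupancy(self):
        lone = [make_site("M1", 0, 6, 1.0)]
        contested = lone + [make_site("M2", 3, 6, 1.0)]
        model = self._pair_model(1.0, "competition")
        assert occupancy_dp(contested, model) < occupancy_dp(lone, model)


@pytest.mark.parametrize("mode,omega", [
    ("single", 1.0),
    ("competition", 1.0),
    ("cooperative", 7.5),
    ("antagonistic", 0.13),
])
def test_dp_matches_brute_force_on_random_instances(mode, omega):
    rng = np.random.default_rng(hash(mode) % 2**31)
    names = ("M1",) if mode == "single" else ("M1", "M2")
    pwms = [PWM(n, np.full((6, 4), 0.25), pseudocount=0.0) for n in names]
    for trial in range(60):
        n = int(rng.integers(0, 13))
        sites = random_sites(rng, n, motif_names=names)
        d_T = int(rng.choice([10, 30, 150]))
        gammas = list(10.0 ** rng.uniform(-1, 4, size=len(names)))
        model = BindingModel(pwms, gammas, omega=omega, d_T=d_T, mode=mode)
        bf = occupancy_brute_force(sites, model)
        dp = occupancy_dp(sites, model)
        assert dp == pytest.approx(bf, rel=1e-9, abs=1e-12)


@st.composite
def _site_lists(draw):
    n = draw(st.integers(min_value=0, max_value=10))
    sites = []
    for _ in range(n):
        length = draw(st.integers(5, 10))
        start = draw(st.integers(0, 180))
        motif = draw(st.sampled_from(["M1", "M2"]))
        rel = draw(st.floats(0.01, 1.0, allow_nan=False))
        sites.append(make_site(motif, start, length, rel))
    return sorted(sites, key=lambda s: (s.start, s.end))


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    sites=_site_lists(),
    log_g0=st.floats(-1, 4),
    log_g1=st.floats(-1, 4),
    log_omega=st.floats(-2, 2),
    d_T=st.sampled_from([10, 30, 150]),
)
def test_dp_brute_force_equivalence_property(sites, log_g0, log_g1, log_omega, d_T):
    """For arbitrary overlapping site sets and parameters, the DP reproduces
    the explicit configuration sum."""
    omega = 10.0 ** log_omega
    mode = "cooperative" if omega >= 1 else "antagonistic"
    pwms = [
        PWM("M1", np.full((6, 4), 0.25), pseudocount=0.0),
        PWM("M2", np.full((6, 4), 0.25), pseudocount=0.0),
    ]
    model = BindingModel(
        pwms, [10.0 ** log_g0, 10.0 ** log_g1], omega=omega, d_T=d_T, mode=mode
    )
    assert occupancy_dp(sites, model) == pytest.approx(
        occupancy_brute_force(sites, model), rel=1e-9, abs=1e-12
    )


def test_occupancy_bounded_and_monotone_in_gamma():
    rng = np.random.default_rng(4)
    pwm = PWM("M1", np.full((6, 4), 0.25), pseudocount=0.0)
    for _ in range(20):
        sites = random_sites(rng, int(rng.integers(1, 10)), motif_names=("M1",))
        occs = [
            occupancy_dp(sites, BindingModel([pwm], [g]))
            for g in (0.1, 1.0, 10.0, 1e3, 1e5)
        ]
        n_max = len(sites)
        assert all(0 <= o <= n_max for o in occs)
        assert all(b >= a - 1e-12 for a, b in zip(occs, occs[1:]))


def test_extreme_gamma_does_not_overflow():
    sites = [make_site("M1", 12 * i, 6, 1.0) for i in range(40)]
    pwm = PWM("M1", np.full((6, 4), 0.25), pseudocount=0.0)
    occ = occupancy_dp(sites, BindingModel([pwm], [1e5]))
    assert np.isfinite(occ)
    assert occ == pytest.approx(40.0, rel=1e-3)


class TestPredictWindow:
    def test_window_without_sites_scores_zero(self, primary_pwm):
        model = BindingModel([primary_pwm], [10.0])
        assert predict_window("GT" * 100, model) == 0.0

    def test_saturated_consensus_site(self, primary_pwm):
        model = BindingModel([primary_pwm], [1e4])
        seq = "GT" * 40 + primary_pwm.consensus + "GT" * 40
        assert predict_window(seq, model) >= 0.999

    def test_cooperative_interaction_raises_score(self, primary_pwm, secondary_pwm):
        seq = (
            "GT" * 30
            + primary_pwm.consensus
            + "GT" * 10
            + secondary_pwm.consensus
            + "GT" * 30
        )
        coop = BindingModel(
            [primary_pwm, secondary_pwm], [1.0, 1.0], omega=5.0, d_T=150, mode="cooperative"
        )
        neutral = BindingModel(
            [primary_pwm, secondary_pwm], [1.0, 1.0], omega=1.0, d_T=150, mode="competition"
        )
        assert predict_window(seq, coop) > predict_window(seq, neutral)


class TestBindingModelValidation:
    def test_mode_and_omega_constraints(self, primary_pwm, secondary_pwm):
        with pytest.raises(ValueError):
            BindingModel([primary_pwm], [1.0], omega=2.0, mode="single")
        with pytest.raises(ValueError):
            BindingModel([primary_pwm, secondary_pwm], [1, 1], omega=0.5, mode="cooperative")
        with pytest.raises(ValueError):
            BindingModel([primary_pwm, secondary_pwm], [1, 1], omega=2.0, mode="antagonistic")
        with pytest.raises(ValueError):
            BindingModel([primary_pwm], [1.0], mode="competition")
        with pytest.raises(ValueError):
            BindingModel([primary_pwm], [-1.0])
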