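import numpy as np
import pytest

from chainthermo import (
    DrivenChain,
    energy_family,
    crooks_report,
    hysteresis,
    jarzynski_exact,
    jarzynski_mc,
    reversal_energy_family,
    second_law_gap,
    time_reversal,
    trajectory_probability,
    trajectory_ratio_check,
    work_distribution,
)
from conftest import make_random_chain


class TestJarzynskiExact:
    def test_counterexample_closed_form(self, counterexample3):
        # W depends only on x0: 0.5*1 + 0.2*(3/2) + 0.3*(2/3) = 1
        chain, family = counterexample3
        assert jarzynski_exact(chain, family) == pytest.approx(1.0, abs=1e-12)

    def test_db2_closed_form(self, db2):
        # W depends only on x1: (2/3)(3/4) + (1/3)(3/2) = 1
        chain, family = db2
        assert jarzynski_exact(chain, family) == pytest.approx(1.0, abs=1e-12)

    def test_holds_under_arbitrary_gauges(self, db2):
        chain, _ = db2
        rng = np.random.default_rng(5)
        for _ in range(10):
            family = energy_family(chain, gauges=rng.normal(size=3))
            assert jarzynski_exact(chain, family) == pytest.approx(1.0, abs=1e-9)

    def test_reducible_matrix_refused(self):
        from chainthermo import EnergyFamily

        chain = DrivenChain(
            states=(0, 1), p0=np.array([0.5, 0.5]), matrices=(np.eye(2),)
        )
        family = EnergyFamily(
            states=(0, 1),
            beta=1.0,
            energies=np.full((2, 2), np.log(2)),
            gauges=np.zeros(2),
        )
        with pytest.raises(ValueError, match="reducible"):
            jarzynski_exact(chain, family)


class TestJarzynskiMonteCarlo:
    def test_within_five_sigma_of_unity(self, db2):
        chain, family = db2
        est, se = jarzynski_mc(chain, family, n=100_000, seed=123)
        assert se > 0
        assert abs(est - 1.0) <= 5 * se

    def test_deterministic_chain_has_zero_error(self):
        M = np.roll(np.eye(3), 1, axis=0)
        chain = DrivenChain(
            states=(0, 1, 2), p0=np.array([1e-12, 1e-12, 1.0 - 2e-12]),
            matrices=(M,),
        )
        family = energy_family(chain)
        est, se = jarzynski_mc(chain, family, n=1000, seed=0)
        # effectively a point-mass start: every sampled path is identical
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_reproducible(self, db2):
        chain, family = db2
        a = jarzynski_mc(chain, family, n=5000, seed=9)
        b = jarzynski_mc(chain, family, n=5000, seed=9)
        assert a == b


class TestTrajectoryRatio:
    def test_hand_values_on_db2(self, db2):
        chain, family = db2
        Y = time_reversal(chain)  # equals the auxiliary chain here
        px = trajectory_probability(chain, (0, 0, 0))
        py = trajectory_probability(Y, (0, 0, 0))
        assert px == pytest.approx(0.42)
        assert py == pytest.approx(0.315)
        assert px / py == pytest.approx(4 / 3)  # = exp(W - deltaF)

    def test_identity_on_fixtures(self, db2, counterexample3):
        for chain, family in (db2, counterexample3):
            assert trajectory_ratio_check(chain, family) <= 1e-12

    def test_identity_on_random_chains(self):
        for seed in range(30):
            chain = make_random_chain(seed)
            family = energy_family(chain)
            assert trajectory_ratio_check(chain, family) <= 1e-10

    def test_equal_energies_mean_equal_path_probabilities(self, flat_chain):
        # with all p_n equal and all E_n equal, W = deltaF = 0, so forward
        # and reversed path probabilities coincide trajectory by trajectory
        chain, family = flat_chain
        Y = time_reversal(chain)
        from chainthermo import enumerate_trajectories

        for x, px in enumerate_trajectories(chain):
            assert trajectory_probability(Y, x.reversed()) == pytest.approx(
                px, abs=1e-12
            )


class TestHysteresis:
    def test_db2_hand_value(self, db2):
        chain, family = db2
        assert hysteresis(chain, family, (0, 0, 0)) == pytest.approx(np.log(4 / 3))

    def test_zero_when_work_equals_delta_f(self, flat_chain):
        chain, family = flat_chain
        for x in [(0, 0, 0), (0, 1, 0), (1, 0, 1)]:
            assert hysteresis(chain, family, x) == pytest.approx(0.0, abs=1e-12)

    def test_refused_without_detailed_balance(self, cycle3):
        family = energy_family(cycle3)
        with pytest.raises(ValueError, match="trajectory_ratio_check"):
            hysteresis(cycle3, family, (0, 1, 2))


class TestWorkDistribution:
    def test_counterexample_forward_atoms(self, counterexample3):
        chain, family = counterexample3
        wd = work_distribution(chain, family)
        np.testing.assert_allclose(
            wd.support, sorted([np.log(2 / 3), 0.0, np.log(3 / 2)]), atol=1e-12
        )
        assert wd.probability_of(0.0) == pytest.approx(0.5)
        assert wd.probability_of(np.log(2 / 3)) == pytest.approx(0.2)
        assert wd.probability_of(np.log(3 / 2)) == pytest.approx(0.3)

    def test_counterexample_backward_is_point_mass(self, counterexample3):
        chain, family = counterexample3
        Y = time_reversal(chain)
        wd = work_distribution(Y, reversal_energy_family(family))
        assert wd.support.size == 1
        assert wd.support[0] == pytest.approx(0.0, abs=1e-12)
        assert wd.probabilities[0] == pytest.approx(1.0, abs=1e-12)

    def test_db2_forward_atoms(self, db2):
        chain, family = db2
        wd = work_distribution(chain, family)
        assert wd.probability_of(np.log(4 / 3)) == pytest.approx(2 / 3)
        assert wd.probability_of(np.log(2 / 3)) == pytest.approx(1 / 3)

    def test_distributions_normalize(self, db2, counterexample3):
        for chain, family in (db2, counterexample3):
            for c, f in ((chain, family),
                         (time_reversal(chain), reversal_energy_family(family))):
                wd = work_distribution(c, f)
                assert wd.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_db2_supports_mirror_under_negation(self, db2):
        chain, family = db2
        fwd = work_distribution(chain, family)
        bwd = work_distribution(
            time_reversal(chain), reversal_energy_family(family)
        )
        np.testing.assert_allclose(
            np.sort(fwd.support), np.sort(-bwd.support), atol=1e-12
        )


class TestCrooks:
    def test_db2_report_holds_with_hand_numbers(self, db2):
        chain, family = db2
        rep = crooks_report(chain, family)
        assert rep.holds and rep.p0_equals_p1
        assert rep.k == pytest.approx(0.0, abs=1e-12)
        row = rep.table.set_index(rep.table["work"].round(9)).loc[
            round(np.log(4 / 3), 9)
        ]
        assert row["prob_forward"] == pytest.approx(2 / 3)
        assert row["prob_backward"] == pytest.approx(1 / 2)
        assert row["observed_ratio"] == pytest.approx(4 / 3)
        assert row["predicted_ratio"] == pytest.approx(4 / 3)

    def test_counterexample_breaks_exactly_as_predicted(self, counterexample3):
        chain, family = counterexample3
        rep = crooks_report(chain, family)
        assert not rep.p0_equals_p1
        assert not rep.holds
        by_work = {round(w, 9): r for w, r in
                   zip(rep.table["work"], rep.table.to_dict(orient="records"))}
        wB, wC = round(np.log(2 / 3), 9), round(np.log(3 / 2), 9)
        assert not by_work[wB]["defined"]
        assert not by_work[wC]["defined"]
        at_zero = by_work[0.0]
        assert at_zero["defined"]
        assert at_zero["observed_ratio"] == pytest.approx(0.5)
        assert at_zero["predicted_ratio"] == pytest.approx(1.0)

    def test_flat_chain_single_atom(self, flat_chain):
        chain, family = flat_chain
        rep = crooks_report(chain, family)
        assert rep.holds
        assert len(rep.table) == 1
        assert rep.table.loc[0, "work"] == pytest.approx(0.0, abs=1e-12)
        assert rep.table.loc[0, "observed_ratio"] == pytest.approx(1.0)

    def test_holds_on_random_reversible_equilibrated_chains(self):
        for seed in range(20):
            chain = make_random_chain(
                seed, mode="detailed_balance", equilibrated=True
            )
            rep = crooks_report(chain, energy_family(chain))
            assert rep.holds, f"seed {seed}: max rel {rep.max_relative_error}"


class TestSecondLaw:
    def test_counterexample_gap_value(self, counterexample3):
        chain, family = counterexample3
        assert second_law_gap(chain, family) == pytest.approx(
            0.1 * np.log(1.5), abs=1e-12
        )

    def test_flat_chain_gap_is_exactly_zero(self, flat_chain):
        chain, family = flat_chain
        assert second_law_gap(chain, family) == pytest.approx(0.0, abs=1e-13)

    def test_nonnegative_on_random_chains(self):
        for seed in range(100):
            chain = make_random_chain(seed)
            assert second_law_gap(chain, energy_family(chain)) >= -1e-12
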