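"""Tests of the isofemale-line simulator and the Monte-Carlo segregation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cotrans.model import (
    InfectionStatus,
    StrainParams,
    build_transition_matrix,
)
from cotrans.simulate import (
    NullDistribution,
    empirical_p_value,
    null_distribution,
    simulate_lineages,
)

U, S1, S2, CO = InfectionStatus


def _codes_by_generation(table):
    return np.stack(
        [table.status_codes(g) for g in range(table.n_generations + 1)]
    )


class TestSimulateLineages:
    def test_perfect_transmission_keeps_all_lines_coinfected(self):
        table = simulate_lineages(StrainParams(1.0, 1.0), 40, 4, seed=0)
        assert table.coinfected_count(4) == 40

    def test_zero_transmission_loses_everything_after_one_generation(self):
        table = simulate_lineages(StrainParams(0.0, 0.0), 10, 3, seed=0)
        codes = _codes_by_generation(table)
        assert np.all(codes[1:] == int(U))
        assert np.all(codes[0] == int(CO))

    def test_record_count_and_one_status_per_line_generation(self, field_params):
        table = simulate_lineages(field_params, 40, 4, seed=5)
        assert len(table.records) == 40 * 5
        counts = table.records.groupby(["line_id", "generation"]).size()
        assert (counts == 1).all()

    def test_no_strain_regain_and_uninfected_absorbing(self, field_params):
        table = simulate_lineages(field_params, 200, 6, seed=7)
        codes = _codes_by_generation(table)
        has1 = (codes == int(S1)) | (codes == int(CO))
        has2 = (codes == int(S2)) | (codes == int(CO))
        # a strain absent at generation g is absent at all later generations
        assert not np.any(~has1[:-1] & has1[1:])
        assert not np.any(~has2[:-1] & has2[1:])

    def test_coinfected_count_non_increasing_within_simulation(self, field_params):
        table = simulate_lineages(field_params, 100, 8, seed=11)
        per_gen = [table.coinfected_count(g) for g in range(9)]
        assert all(a >= b for a, b in zip(per_gen, per_gen[1:]))

    def test_seed_reproducibility(self, field_params):
        a = simulate_lineages(field_params, 40, 4, seed=42)
        b = simulate_lineages(field_params, 40, 4, seed=42)
        c = simulate_lineages(field_params, 40, 4, seed=43)
        pd.testing.assert_frame_equal(a.records, b.records)
        assert not a.records.equals(c.records)

    def test_singly_infected_founder_marginal(self):
        table = simulate_lineages(
            StrainParams(0.8, 0.5), 4000, 1, founder_status=S1, seed=3
        )
        frac = np.mean(table.status_codes(1) == int(S1))
        se = np.sqrt(0.8 * 0.2 / 4000)
        assert frac == pytest.approx(0.8, abs=4 * se)

    def test_mean_final_count_matches_analytic(self, field_params):
        """Simulation mean agrees with the chain's (p1 p2)^n prediction."""
        null = null_distribution(field_params, 40, 4, 10_000, seed=17)
        q = (0.96 * 0.943) ** 4
        se = np.sqrt(40 * q * (1 - q) / 10_000)
        assert null.mean == pytest.approx(40 * q, abs=3 * se)

    def test_lineage_tsv_roundtrip(self, field_params, tmp_path):
        table = simulate_lineages(field_params, 12, 3, seed=9)
        path = tmp_path / "lineages.tsv"
        table.to_tsv(path)
        again = table.from_tsv(path)
        pd.testing.assert_frame_equal(again.records, table.records)
        assert again.params == table.params
        assert (again.n_lines, again.n_generations, again.seed) == (12, 3, 9)


class TestBernoulliMatrixEquivalence:
    def test_induced_row_probabilities_match_matrix_exactly(self, field_params):
        """Per-strain Bernoulli retention induces exactly the matrix rows."""
        m = build_transition_matrix(field_params)
        p1, p2 = field_params.p1, field_params.p2
        for mother in InfectionStatus:
            r1 = p1 if mother.carries_strain1 else 0.0
            r2 = p2 if mother.carries_strain2 else 0.0
            induced = np.array(
                [
                    (1 - r1) * (1 - r2),
                    r1 * (1 - r2),
                    (1 - r1) * r2,
                    r1 * r2,
                ]
            )
            np.testing.assert_allclose(induced, m.row(mother), atol=1e-15)

    def test_simulated_frequencies_match_categorical_oracle(self, field_params):
        """Bernoulli-retention simulation is indistinguishable from sampling
        offspring statuses directly from the matrix row."""
        n = 10_000
        m = build_transition_matrix(field_params)
        table = simulate_lineages(field_params, n, 1, seed=23)
        bern = np.bincount(table.status_codes(1), minlength=4) / n
        oracle_rng = np.random.default_rng(24)
        cat = np.bincount(
            oracle_rng.choice(4, size=n, p=m.row(CO)), minlength=4
        ) / n
        for s in range(4):
            p = m.row(CO)[s]
            tol = 4 * np.sqrt(max(p * (1 - p), 1e-4) / n) * 2
            assert bern[s] == pytest.approx(p, abs=tol)
            assert cat[s] == pytest.approx(p, abs=tol)


class TestNullDistribution:
    def test_perfect_transmission_null_is_degenerate(self):
        null = null_distribution(StrainParams(1.0, 1.0), 40, 4, 500, seed=0)
        assert np.all(null.counts == 40)

    def test_counts_bounded_and_sized(self, field_params):
        null = null_distribution(field_params, 40, 4, 1000, seed=1)
        assert len(null.counts) == 1000
        assert null.counts.min() >= 0 and null.counts.max() <= 40

    def test_single_generation_counts_are_binomial(self):
        """10 lines, one generation, p1 = p2 = 0.5: counts ~ Binomial(10, 0.25)."""
        null = null_distribution(StrainParams(0.5, 0.5), 10, 1, 1000, seed=2)
        observed = np.bincount(null.counts, minlength=11).astype(float)
        expected = stats.binom.pmf(np.arange(11), 10, 0.25) * 1000
        # merge sparse upper tail so every bin has expected count >= ~5
        cut = 7
        obs = np.append(observed[:cut], observed[cut:].sum())
        exp = np.append(expected[:cut], expected[cut:].sum())
        gof = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert gof.pvalue > 0.01

    def test_reproducible_given_seed(self, field_params):
        a = null_distribution(field_params, 40, 4, 200, seed=3)
        b = null_distribution(field_params, 40, 4, 200, seed=3)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_tabulate_sums_to_n_sims(self, field_params):
        null = null_distribution(field_params, 40, 4, 300, seed=4)
        assert null.tabulate().sum() == 300


class TestEmpiricalPValue:
    def test_hand_enumeration_with_add_one_rule(self, field_params):
        null = NullDistribution(
            counts=np.arange(1, 10), n_sims=9, n_lines=40, n_generations=4,
            params=field_params,
        )
        res = empirical_p_value(null, 2)
        assert empirical_p_value(null, 2, "lower").p_value == pytest.approx(0.3)
        assert res.p_value == pytest.approx(0.6)
        assert res.p_value_raw == pytest.approx(2 * 2 / 9)

    def test_observed_equal_to_degenerate_null_gives_one(self):
        null = null_distribution(StrainParams(1.0, 1.0), 40, 4, 1000, seed=0)
        assert empirical_p_value(null, 40).p_value == 1.0

    def test_far_below_null_is_significant(self, field_params):
        null = null_distribution(field_params, 40, 4, 1000, seed=1)
        res = empirical_p_value(null, 11)
        assert res.p_value == pytest.approx(2 / 1001)
        assert res.null_mean == pytest.approx(26.9, abs=1.0)

    def test_out_of_range_observation_rejected(self, field_params):
        null = null_distribution(field_params, 40, 4, 100, seed=1)
        with pytest.raises(ValueError, match=r"\[0, 40\]"):
            empirical_p_value(null, 41)
        with pytest.raises(ValueError, match="sidedness"):
            empirical_p_value(null, 10, "sideways")

    def test_p_values_conservative_under_null(self, field_params):
        """Under the independence null, Monte-Carlo p-values are stochastically
        at least uniform (the add-one, doubled-tail rule never anti-conservative)."""
        rng = np.random.default_rng(31)
        pvals = []
        for _ in range(500):
            obs = null_distribution(field_params, 40, 4, 1, rng=rng).counts[0]
            null = null_distribution(field_params, 40, 4, 999, rng=rng)
            pvals.append(empirical_p_value(null, obs).p_value)
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05, 0.1, 0.2, 0.5):
            se = np.sqrt(alpha * (1 - alpha) / 500)
            assert np.mean(pvals <= alpha) <= alpha + 3 * se
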