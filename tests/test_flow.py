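"""Forward model: activities, the linear link, and combination effects.

Oracle equivalence checks compare the vectorized implementation against
independently coded term-by-term summations on random small instances.
"""

import numpy as np
import pytest

from pathflow import (
    ModelParameters,
    baseline_activity,
    combination_delta,
    delta_activity,
    predicted_sensitivity,
    rank_combinations,
    treated_activity,
)

from conftest import random_instance, random_params


# --- independent brute-force oracles ---------------------------------------


def oracle_baseline(m, v, p):
    total = 0.0
    for j in range(len(p.genes)):
        total += m[j] * p.A_m[j] + v[j] * p.A_v[j]
    return total


def oracle_treated(m, v, p, d):
    total = 0.0
    for j in range(len(p.genes)):
        total += (m[j] * p.A_m[j] + v[j] * p.A_v[j]) * p.rho[j, d] * p.alpha[d]
    return total


def oracle_combination(m, v, p, d1, d2):
    """Sequential application: attenuate with d1, then d2, subtract from
    the baseline."""
    baseline = oracle_baseline(m, v, p)
    left = 0.0
    for j in range(len(p.genes)):
        a_j = m[j] * p.A_m[j] + v[j] * p.A_v[j]
        after_d1 = a_j * p.rho[j, d1] * p.alpha[d1]
        after_both = after_d1 * p.rho[j, d2] * p.alpha[d2]
        left += after_both
    return baseline - left


def single_gene_params(A_m=100.0, rho=1.0, alpha=0.2, b=0.0):
    return ModelParameters(
        genes=("A",),
        drugs=("inhibitor",),
        A_m=[A_m],
        A_v=[0.0],
        rho=[[rho]],
        alpha=[alpha],
        b=[b],
    )


class TestSingleDrugActivities:
    def test_no_alterations_give_zero_baseline(self):
        p = single_gene_params()
        assert baseline_activity([0], [0], p) == 0.0

    def test_mutation_increases_activity_by_its_contribution(self):
        # one mutant gene contributing +100 of pathway activity
        p = single_gene_params(A_m=100.0)
        assert baseline_activity([1], [0], p) == 100.0

    def test_partial_inhibition_leaves_fraction(self):
        # rho*alpha = 0.2 on the altered gene: 20 of 100 left after drug
        p = single_gene_params(A_m=100.0, rho=1.0, alpha=0.2)
        assert treated_activity([1], [0], p, "inhibitor") == pytest.approx(20.0)
        assert delta_activity([1], [0], p, "inhibitor").delta == pytest.approx(80.0)

    def test_no_inhibition_means_treated_equals_baseline(self, rng):
        _, _, p = random_instance(rng)
        p.rho[:] = 1.0
        p.alpha[:] = 1.0
        m = np.array([1, 0, 1, 1])
        v = np.array([0, 1, 1, 0])
        assert treated_activity(m, v, p, p.drugs[0]) == pytest.approx(
            baseline_activity(m, v, p)
        )

    def test_all_zero_profile_gives_zero_delta(self, rng):
        _, _, p = random_instance(rng)
        z = np.zeros(len(p.genes))
        assert delta_activity(z, z, p, p.drugs[0]).delta == 0.0

    def test_unknown_drug_rejected(self):
        p = single_gene_params()
        with pytest.raises(KeyError):
            treated_activity([1], [0], p, "nonesuch")

    def test_gene_mismatch_rejected(self):
        p = single_gene_params()
        with pytest.raises(ValueError):
            baseline_activity([1, 0], [0, 0], p)

    def test_breakdown_consistency(self, rng):
        _, _, p = random_instance(rng)
        m = (rng.random(4) < 0.5).astype(float)
        v = (rng.random(4) < 0.5).astype(float)
        br = delta_activity(m, v, p, p.drugs[1])
        assert br.delta == pytest.approx(br.baseline - br.treated, abs=1e-12)
        assert sum(c for _, c in br.per_gene) == pytest.approx(br.baseline)


class TestPredictedSensitivity:
    def test_intercept_only(self):
        p = single_gene_params(b=-3.0)
        assert predicted_sensitivity([0], [0], p, "inhibitor") == pytest.approx(3.0)

    def test_fig_scenario(self):
        p = single_gene_params(A_m=100.0, rho=1.0, alpha=0.2, b=0.0)
        assert predicted_sensitivity([1], [0], p, "inhibitor") == pytest.approx(80.0)

    def test_link_inverts_delta(self, rng):
        _, _, p = random_instance(rng)
        p.k = 2.0
        m = np.array([1, 1, 0, 0])
        v = np.array([0, 0, 1, 0])
        d = p.drugs[2]
        br = delta_activity(m, v, p, d)
        expected = (br.delta - p.b[2]) / 2.0
        assert predicted_sensitivity(m, v, p, d) == pytest.approx(expected)


class TestOracleEquivalence:
    def test_thousand_random_instances(self):
        """delta and combination agree with term-by-term oracles to 1e-10."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            G = rng.integers(1, 6)
            D = rng.integers(2, 5)
            genes = tuple(f"g{j}" for j in range(G))
            drugs = tuple(f"d{j}" for j in range(D))
            p = random_params(rng, genes, drugs)
            m = (rng.random(G) < 0.5).astype(float)
            v = (rng.random(G) < 0.5).astype(float)
            d1, d2 = rng.integers(D), rng.integers(D)
            got = delta_activity(m, v, p, drugs[d1]).delta
            want = oracle_baseline(m, v, p) - oracle_treated(m, v, p, d1)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-12)
            got_c = combination_delta(m, v, p, drugs[d1], drugs[d2])
            want_c = oracle_combination(m, v, p, d1, d2)
            assert got_c == pytest.approx(want_c, rel=1e-10, abs=1e-12)


class TestCombination:
    def test_symmetry(self, rng):
        _, _, p = random_instance(rng)
        m = np.array([1, 0, 1, 0])
        v = np.array([0, 1, 0, 0])
        a = combination_delta(m, v, p, p.drugs[0], p.drugs[2])
        b = combination_delta(m, v, p, p.drugs[2], p.drugs[0])
        assert a == b

    def test_inert_partner_reduces_to_single_drug(self, rng):
        _, _, p = random_instance(rng)
        p.rho[:, 1] = 1.0
        p.alpha[1] = 1.0  # drug 1 passes everything through: inert partner
        m = np.array([1, 1, 0, 1])
        v = np.array([0, 0, 1, 0])
        combo = combination_delta(m, v, p, p.drugs[0], p.drugs[1])
        single = delta_activity(m, v, p, p.drugs[0]).delta
        assert combo == pytest.approx(single, rel=1e-12)

    def test_two_half_drugs_on_unit_activity(self):
        p = ModelParameters(
            genes=("A",), drugs=("d1", "d2"),
            A_m=[2.0], A_v=[0.0],
            rho=[[1.0, 1.0]], alpha=[0.5, 0.5], b=[0.0, 0.0],
        )
        # activity 2, each drug attenuates by 0.5: 2 * (1 - 0.25) = 1.5
        assert combination_delta([1], [0], p, "d1", "d2") == pytest.approx(1.5)

    def test_self_combination_squares_attenuation(self, rng):
        _, _, p = random_instance(rng)
        m = np.array([1, 0, 1, 1])
        v = np.array([1, 1, 0, 0])
        for d_idx, d in enumerate(p.drugs):
            a = m * p.A_m + v * p.A_v
            want = float((a * (1 - (p.rho[:, d_idx] * p.alpha[d_idx]) ** 2)).sum())
            assert combination_delta(m, v, p, d, d) == pytest.approx(want, rel=1e-12)

    def test_dominance_with_nonnegative_terms(self, rng):
        """With all per-gene terms >= 0 a pair removes at least as much
        activity as either drug alone."""
        _, _, p = random_instance(rng)
        p.A_m = np.abs(p.A_m)
        p.A_v = np.abs(p.A_v)
        m = np.array([1, 1, 1, 0])
        v = np.array([0, 1, 0, 1])
        for i in range(len(p.drugs)):
            for j in range(len(p.drugs)):
                combo = combination_delta(m, v, p, p.drugs[i], p.drugs[j])
                singles = max(
                    delta_activity(m, v, p, p.drugs[i]).delta,
                    delta_activity(m, v, p, p.drugs[j]).delta,
                )
                assert combo >= singles - 1e-12

    def test_linearity_in_contributions(self, rng):
        _, _, p = random_instance(rng)
        m = np.array([1, 0, 1, 0])
        v = np.array([0, 1, 1, 0])
        d = p.drugs[0]
        before = delta_activity(m, v, p, d).delta
        p.A_m = p.A_m * 2
        p.A_v = p.A_v * 2
        assert delta_activity(m, v, p, d).delta == pytest.approx(2 * before)


class TestRankCombinations:
    def test_three_drugs_give_three_pairs(self, rng):
        genes = ("g0",)
        drugs = ("a", "b", "c")
        p = random_params(rng, genes, drugs)
        out = rank_combinations(np.array([1]), np.array([0]), p)
        assert len(out) == 3
        assert {frozenset((d1, d2)) for d1, d2, _ in out} == {
            frozenset(x) for x in (("a", "b"), ("a", "c"), ("b", "c"))
        }

    def test_zero_baseline_all_effects_zero_lexicographic(self, rng):
        _, _, p = random_instance(rng)
        z = np.zeros(len(p.genes))
        out = rank_combinations(z, z, p)
        assert all(eff == 0.0 for _, _, eff in out)
        assert out == sorted(out, key=lambda t: (t[0], t[1]))

    def test_fully_transparent_pair_scores_exactly_zero(self):
        """Two drugs that leave every altered gene untouched (rho*alpha = 1)
        produce a pair effect of exactly 0."""
        p = ModelParameters(
            genes=("g0", "g1"), drugs=("x", "y", "z"),
            A_m=[3.0, -2.0], A_v=[1.0, 0.5],
            rho=np.array([[1.0, 1.0, 0.3], [1.0, 1.0, 0.8]]),
            alpha=[1.0, 1.0, 0.9], b=[0.0, 0.0, 0.0],
        )
        m = np.array([1, 1])
        v = np.array([1, 0])
        out = dict(
            ((d1, d2), eff) for d1, d2, eff in rank_combinations(m, v, p)
        )
        assert out[("x", "y")] == 0.0
        assert out[("x", "z")] != 0.0

    def test_exclusion_and_minimum_pair_count(self, rng):
        _, _, p = random_instance(rng)  # 3 drugs
        m = np.array([1, 0, 0, 1])
        v = np.array([0, 0, 1, 0])
        out = rank_combinations(m, v, p, exclude={p.drugs[0]})
        assert len(out) == 1
        with pytest.raises(ValueError):
            rank_combinations(m, v, p, exclude=set(p.drugs[:2]))

    def test_sorted_ascending_most_negative_first(self, rng):
        _, _, p = random_instance(rng)
        m = np.array([1, 1, 0, 1])
        v = np.array([0, 1, 1, 0])
        out = rank_combinations(m, v, p)
        effects = [eff for _, _, eff in out]
        assert effects == sorted(effects)
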