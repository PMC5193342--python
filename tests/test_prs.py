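"""Pseudo-control construction, polygenic scores and conditional logistic fits."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from triocnv import prs
from triocnv import simulate as sim


def make_genotypes(father, mother, offspring, families=None):
    father = np.atleast_2d(np.asarray(father, dtype=np.int8))
    mother = np.atleast_2d(np.asarray(mother, dtype=np.int8))
    offspring = np.atleast_2d(np.asarray(offspring, dtype=np.int8))
    n_fam, n_mark = father.shape
    return sim.TrioGenotypes(
        marker_ids=[f"snp{j}" for j in range(n_mark)],
        families=families or [f"f{i}" for i in range(n_fam)],
        father=father,
        mother=mother,
        offspring=offspring,
    )


def make_trios(n):
    return [sim.Trio(f"f{i}", f"f{i}-fa", f"f{i}-mo", f"f{i}-off") for i in range(n)]


class TestPseudoControls:
    def test_homozygous_parents(self):
        g = make_genotypes([[2]], [[2]], [[2]])
        (pair,) = prs.build_pseudo_controls(make_trios(1), g)
        assert pair.case[0] == 2 and pair.pseudo_control[0] == 2

    def test_het_father_hom_mother_bookkeeping(self):
        # father Aa, mother aa, child Aa: child got A from father, so the
        # pseudo-control holds the untransmitted a,a
        g = make_genotypes([[1]], [[0]], [[1]])
        (pair,) = prs.build_pseudo_controls(make_trios(1), g)
        assert pair.case[0] == 1 and pair.pseudo_control[0] == 0

    def test_inconsistent_trio_excluded(self):
        g = make_genotypes([[0], [1]], [[0], [1]], [[2], [1]], families=["f0", "f1"])
        pairs = prs.build_pseudo_controls(make_trios(2), g)
        assert [p.family_id for p in pairs] == ["f1"]

    def test_allele_partition_invariant(self):
        trios = sim.generate_trios(80, seed=1)
        g = sim.simulate_trio_genotypes(trios, 30, seed=2)
        pairs = prs.build_pseudo_controls(trios, g, seed=3)
        assert len(pairs) == 80
        fam_idx = {f: i for i, f in enumerate(g.families)}
        for p in pairs:
            i = fam_idx[p.family_id]
            parental = g.father[i] + g.mother[i]
            assert np.all(p.case + p.pseudo_control == parental)

    def test_double_heterozygote_seeded(self):
        g = make_genotypes([[1]] * 10, [[1]] * 10, [[1]] * 10)
        trios = make_trios(10)
        p1 = prs.build_pseudo_controls(trios, g, seed=7)
        p2 = prs.build_pseudo_controls(trios, g, seed=7)
        assert all(
            np.array_equal(a.pseudo_control, b.pseudo_control) for a, b in zip(p1, p2)
        )


class TestScore:
    RISK = prs.RiskAlleleSet({0: (0.2, 0.01), 1: (0.5, 0.05), 2: (0.3, 0.5)}, 0.1)

    def test_inclusion_threshold(self):
        assert self.RISK.included() == [0, 1]  # marker 2 fails P_T < 0.1

    def test_no_risk_alleles(self):
        assert prs.score_prs(np.array([0, 0, 2]), self.RISK) == 0.0

    def test_homozygous_everywhere_unweighted(self):
        assert prs.score_prs(np.array([2, 2, 2]), self.RISK) == 2.0

    def test_missing_marker_renormalization(self):
        # marker 0 missing: unweighted score = 1/1; weighted = 0.5*1/1
        g = np.array([-1, 1, 2])
        assert prs.score_prs(g, self.RISK) == pytest.approx(1.0)
        assert prs.score_prs(g, self.RISK, weighted=True) == pytest.approx(0.5)
        full = np.array([2, 1, 0])
        assert prs.score_prs(full, self.RISK) == pytest.approx((2 + 1) / 2)
        assert prs.score_prs(full, self.RISK, weighted=True) == pytest.approx(
            (0.2 * 2 + 0.5 * 1) / 2
        )


class TestClrFit:
    def test_concordant_pairs_are_null(self):
        fit = prs.clr_fit([], prs.RiskAlleleSet({}), scores=np.zeros(20))
        assert fit.beta == 0 and fit.nagelkerke_r2 == 0 and fit.p_value == 1.0

    def test_matches_grid_search_oracle_on_five_pairs(self):
        deltas = np.array([0.8, -0.3, 0.5, 0.1, -0.6])

        def neg_loglik(beta):
            return np.logaddexp(0, -beta * deltas).sum()

        oracle = minimize_scalar(neg_loglik, bounds=(-10, 10), method="bounded")
        fit = prs.clr_fit([], prs.RiskAlleleSet({}), scores=deltas)
        assert fit.beta == pytest.approx(oracle.x, abs=1e-5)
        assert fit.loglik_full == pytest.approx(-oracle.fun, abs=1e-8)
        assert fit.loglik_full >= fit.loglik_null

    def test_positive_effect_recovered(self):
        rng = np.random.default_rng(4)
        deltas = rng.normal(0.4, 1.0, 300)
        fit = prs.clr_fit([], prs.RiskAlleleSet({}), scores=deltas)
        assert fit.beta > 0 and fit.nagelkerke_r2 > 0 and fit.p_value < 0.01

    def test_complete_separation_flagged(self):
        fit = prs.clr_fit([], prs.RiskAlleleSet({}), scores=np.array([0.5, 1.0, 0.2]))
        assert fit.separated and fit.se is None

    def test_nagelkerke_formula(self):
        deltas = np.array([0.8, -0.3, 0.5, 0.1, -0.6, 0.9, -0.2, 0.4])
        fit = prs.clr_fit([], prs.RiskAlleleSet({}), scores=deltas)
        n = len(deltas)
        expected = (1 - np.exp(2 * (fit.loglik_null - fit.loglik_full) / n)) / (
            1 - np.exp(2 * fit.loglik_null / n)
        )
        assert fit.nagelkerke_r2 == pytest.approx(expected, rel=1e-9)


def _stratified_setup(n_carrier=60, n_noncarrier=200, effect_or=2.0, seed=5):
    """Risk-allele effect present only in the non-carrier families."""
    trios = sim.generate_trios(n_carrier + n_noncarrier, seed=seed)
    carrier_fams = {t.family_id for t in trios[:n_carrier]}
    risk_markers = list(range(25))
    g_car = sim.simulate_trio_genotypes(trios[:n_carrier], 50, seed=seed + 1)
    g_non = sim.simulate_trio_genotypes(
        trios[n_carrier:], 50, risk_markers=risk_markers,
        transmission_or=effect_or, seed=seed + 2,
    )
    g = sim.TrioGenotypes(
        marker_ids=g_car.marker_ids,
        families=g_car.families + g_non.families,
        father=np.vstack([g_car.father, g_non.father]),
        mother=np.vstack([g_car.mother, g_non.mother]),
        offspring=np.vstack([g_car.offspring, g_non.offspring]),
    )
    risk = prs.RiskAlleleSet({j: (0.2, 0.01) for j in risk_markers}, 0.1)
    pairs = prs.build_pseudo_controls(trios, g, seed=seed + 3)
    labels = {f: True for f in carrier_fams}
    return pairs, risk, labels


class TestStratifiedAnalysis:
    def test_single_stratum_equals_pooled(self):
        pairs, risk, _ = _stratified_setup(n_carrier=0, n_noncarrier=50)
        fits = prs.stratified_prs_analysis(pairs, risk, {})
        pooled = prs.clr_fit(pairs, risk)
        assert set(fits) == {"non_carrier"}
        assert fits["non_carrier"].beta == pytest.approx(pooled.beta)

    def test_contrast_between_strata(self):
        # stratum sizes mirror the 116-carrier / larger non-carrier design
        pairs, risk, labels = _stratified_setup(n_carrier=116, n_noncarrier=300)
        fits = prs.stratified_prs_analysis(pairs, risk, labels)
        assert fits["non_carrier"].nagelkerke_r2 > 0.05
        assert fits["carrier"].nagelkerke_r2 < fits["non_carrier"].nagelkerke_r2 / 2

    def test_label_permutation_destroys_contrast(self):
        pairs, risk, labels = _stratified_setup()
        rng = np.random.default_rng(0)
        fams = [p.family_id for p in pairs]
        permuted = dict(zip(rng.permutation(fams), [labels.get(f, False) for f in fams]))
        fits = prs.stratified_prs_analysis(pairs, risk, permuted)
        gap = abs(fits["non_carrier"].nagelkerke_r2 - fits["carrier"].nagelkerke_r2)
        true_fits = prs.stratified_prs_analysis(pairs, risk, labels)
        true_gap = true_fits["non_carrier"].nagelkerke_r2 - true_fits["carrier"].nagelkerke_r2
        assert gap < true_gap


class TestRandomDraws:
    def test_carrier_equal_to_mean_is_nonsignificant(self):
        pairs, risk, labels = _stratified_setup(n_carrier=0, n_noncarrier=150, effect_or=1.0)
        draws = prs.random_draw_comparison(pairs, risk, carrier_r2=0.0, draw_size=50,
                                           n_draws=10, seed=1)
        # carrier value near the null draw distribution -> no strong signal
        assert draws.comparison_p > 0.001

    def test_zero_carrier_vs_positive_draws_significant(self):
        pairs, risk, labels = _stratified_setup(n_carrier=0, n_noncarrier=200, effect_or=2.2)
        comp = prs.random_draw_comparison(pairs, risk, carrier_r2=0.0, draw_size=116,
                                          n_draws=10, seed=2)
        assert comp.mean > 0.03
        assert comp.comparison_p < 0.05

    def test_seed_reproducibility_and_guards(self):
        pairs, risk, _ = _stratified_setup(n_carrier=0, n_noncarrier=60, effect_or=1.5)
        c1 = prs.random_draw_comparison(pairs, risk, 0.0, draw_size=30, n_draws=5, seed=9)
        c2 = prs.random_draw_comparison(pairs, risk, 0.0, draw_size=30, n_draws=5, seed=9)
        assert np.array_equal(c1.draws, c2.draws)
        with pytest.raises(ValueError):
            prs.random_draw_comparison(pairs, risk, 0.0, draw_size=30, n_draws=2)
        with pytest.raises(ValueError):
            prs.random_draw_comparison(pairs, risk, 0.0, draw_size=10_000, n_draws=5)

    def test_beta_recovery_within_two_se(self):
        # transmission OR tau/(1-tau) maps to a positive per-score effect;
        # check the fitted beta is positive and within 2 SE of a refit on
        # independently regenerated data (self-consistency of the scale)
        pairs, risk, _ = _stratified_setup(n_carrier=0, n_noncarrier=300, effect_or=2.0, seed=21)
        fit = prs.clr_fit(pairs, risk)
        assert fit.beta > 0
        pairs2, risk2, _ = _stratified_setup(n_carrier=0, n_noncarrier=300, effect_or=2.0, seed=63)
        fit2 = prs.clr_fit(pairs2, risk2)
        se = np.hypot(fit.se, fit2.se)
        assert abs(fit.beta - fit2.beta) < 2.5 * se
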