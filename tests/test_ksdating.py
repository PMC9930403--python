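"""Ks estimation, mixture fitting, and dating: unit and property tests."""

import numpy as np
import pytest
from scipy import stats

from hopkit import ksdating
from hopkit._codon import AMINO_ACID, SENSE_CODONS, STOP_CODONS
from hopkit.ksdating import (
    CodonAlignment,
    KsEstimate,
    LogKsMixture,
    clock_lrt,
    divergence_time,
    filter_ks,
    fit_log_ks_mixture,
    ks_ng86,
    select_primary_component,
)


def _oracle_codon_sites(codon):
    """Independent per-codon synonymous-site enumerator (stop outcomes
    dropped, each position renormalised over sense changes)."""
    s = 0.0
    for pos in range(3):
        outcomes = []
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            outcomes.append(AMINO_ACID[alt] == AMINO_ACID[codon])
        if outcomes:
            s += sum(outcomes) / len(outcomes)
    return s


class TestKsNg86:
    def test_identical_sequences_have_zero_divergence(self):
        seq = "ATGGCTGAA" * 40
        est = ks_ng86(CodonAlignment("p", seq, seq))
        assert est.ks == 0.0
        assert est.ka == 0.0
        assert est.codons_used == 120

    def test_site_counts_partition_three_per_codon(self):
        rng = np.random.default_rng(7)
        idx = rng.integers(len(SENSE_CODONS), size=200)
        seq = "".join(SENSE_CODONS[i] for i in idx)
        est = ks_ng86(CodonAlignment("p", seq, seq))
        assert est.syn_sites + est.nonsyn_sites == pytest.approx(
            3 * est.codons_used, abs=1e-6
        )

    def test_single_fourfold_difference_matches_enumeration_oracle(self):
        """One third-position change in a 4-fold family (GGA->GGG, both Gly)
        must give Ks = JC(1/S) with S from the independent enumerator."""
        backbone = ["ATG"] + ["GCT"] * 98  # Met + Ala
        seq_a = "".join(backbone + ["GGA"])
        seq_b = "".join(backbone + ["GGG"])
        s_oracle = sum(_oracle_codon_sites(c) for c in backbone) \
            + 0.5 * (_oracle_codon_sites("GGA") + _oracle_codon_sites("GGG"))
        est = ks_ng86(CodonAlignment("p", seq_a, seq_b))
        assert est.syn_sites == pytest.approx(s_oracle, abs=1e-9)
        expected = -0.75 * np.log1p(-4.0 * (1.0 / s_oracle) / 3.0)
        assert est.ks == pytest.approx(expected, rel=1e-12)
        assert est.ka == 0.0

    def test_symmetric_in_the_two_sequences(self, rng):
        for _ in range(20):
            idx = rng.integers(len(SENSE_CODONS), size=60)
            jdx = rng.integers(len(SENSE_CODONS), size=60)
            a = "".join(SENSE_CODONS[i] for i in idx)
            b = "".join(SENSE_CODONS[j] for j in jdx)
            e1 = ks_ng86(CodonAlignment("p", a, b))
            e2 = ks_ng86(CodonAlignment("p", b, a))
            if np.isnan(e1.ks):
                assert np.isnan(e2.ks)
            else:
                assert e1.ks == pytest.approx(e2.ks, rel=1e-12)
            assert e1.syn_sites == pytest.approx(e2.syn_sites, rel=1e-12)

    def test_masked_codons_excluded(self):
        est = ks_ng86(
            CodonAlignment("p", "ATGNNNGCT" + "GAA" * 30,
                           "ATGAAAGCT" + "GAA" * 30)
        )
        assert est.codons_used == 32

    def test_all_invalid_codons_raise(self):
        with pytest.raises(ValueError, match="no valid codon"):
            ks_ng86(CodonAlignment("p", "NNN", "NNN"))


class TestFilterKs:
    def _est(self, ks, flags=frozenset()):
        return KsEstimate("p", ks, 0.0, 100.0, 200.0, 100, flags)

    def test_bounds_inclusive(self):
        values = [0.005, 0.01, 1.9, 2.0, 2.1]
        kept = filter_ks([self._est(v) for v in values])
        assert [e.ks for e in kept] == [0.01, 1.9, 2.0]

    def test_saturated_excluded_with_warning(self):
        ests = [self._est(float("nan"), frozenset({"saturated"}))] * 3
        with pytest.warns(UserWarning, match="all Ks"):
            assert filter_ks(ests) == []

    def test_matches_comprehension_oracle(self, rng):
        ests = [self._est(float(v)) for v in rng.uniform(0, 3, 200)]
        kept = filter_ks(ests, lo=0.1, hi=1.5)
        oracle = [e for e in ests if 0.1 <= e.ks <= 1.5]
        assert kept == oracle

    def test_inverted_bounds_raise(self):
        with pytest.raises(ValueError):
            filter_ks([], lo=2.0, hi=1.0)


class TestMixture:
    def test_single_tight_cluster_selects_one_component(self):
        x = np.full(200, 0.25) * np.exp(1e-4 * np.random.default_rng(0).normal(size=200))
        models, best = fit_log_ks_mixture(x, seed=0)
        assert best.k == 1

    def test_degenerate_identical_values_forced_k1(self):
        models, best = fit_log_ks_mixture(np.full(50, 0.3), seed=0)
        assert best.k == 1
        assert best.sds[0] == pytest.approx(1e-3, rel=1e-6)

    def test_icl_equals_bic_minus_twice_entropy(self):
        """Recompute responsibilities and entropy independently of the
        fitting code and check the ICL identity."""
        rng = np.random.default_rng(3)
        x = np.exp(np.concatenate([
            rng.normal(-2.0, 0.3, 400), rng.normal(0.4, 0.3, 400)
        ]))
        models, _ = fit_log_ks_mixture(x, k_range=range(1, 4), seed=3)
        m = models[2]
        lx = np.log(x)
        dens = m.weights * stats.norm.pdf(lx[:, None], m.means, m.sds)
        resp = dens / dens.sum(axis=1, keepdims=True)
        entropy = -(resp * np.log(np.where(resp > 0, resp, 1.0))).sum()
        assert m.icl == pytest.approx(m.bic - 2 * entropy, rel=1e-9)

    def test_bic_definition(self):
        rng = np.random.default_rng(4)
        x = np.exp(rng.normal(0, 0.4, 300))
        models, _ = fit_log_ks_mixture(x, k_range=[2], seed=4)
        m = models[2]
        assert m.bic == pytest.approx(
            2 * m.log_likelihood - (3 * 2 - 1) * np.log(300), rel=1e-12
        )

    def test_loglik_competitive_with_sklearn(self):
        """The authored EM must reach (at least) the log-likelihood that
        sklearn's GaussianMixture attains on the same data."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        x = np.concatenate([
            rng.normal(-3.0, 0.3, 500), rng.normal(-1.0, 0.4, 500)
        ])
        models, _ = fit_log_ks_mixture(np.exp(x), k_range=[2], seed=5)
        gm = GaussianMixture(2, n_init=5, random_state=0).fit(x[:, None])
        sk_ll = gm.score(x[:, None]) * x.size
        assert models[2].log_likelihood >= sk_ll - 1e-3

    def test_weights_sum_to_one_and_means_sorted(self):
        rng = np.random.default_rng(6)
        x = np.exp(np.concatenate([
            rng.normal(-2, 0.3, 300), rng.normal(0.5, 0.3, 300)
        ]))
        models, _ = fit_log_ks_mixture(x, seed=6)
        for m in models.values():
            assert m.weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(np.diff(m.means) >= 0)

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            fit_log_ks_mixture([0.1] * 5, seed=0)


class TestPrimaryComponent:
    def test_single_component(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(-1, 0.3, 200))
        models, best = fit_log_ks_mixture(x, k_range=[1], seed=0)
        assert select_primary_component(best, x) == 0

    def test_dominant_low_component_selected(self):
        rng = np.random.default_rng(1)
        x = np.exp(np.concatenate([
            rng.normal(np.log(0.03), 0.25, 1700),
            rng.normal(np.log(1.5), 0.25, 300),
        ]))
        models, best = fit_log_ks_mixture(x, k_range=[2], seed=1)
        chosen = select_primary_component(best, x)
        assert best.ks_means[chosen] == pytest.approx(0.03, rel=0.15)

    def test_symmetric_tie_prefers_lower_mean(self):
        # equal-weight components equidistant from the histogram mode
        model = LogKsMixture(
            k=2,
            weights=np.array([0.5, 0.5]),
            means=np.array([-1.0, 1.0]),
            sds=np.array([0.1, 0.1]),
            log_likelihood=0.0, bic=0.0, icl=0.0, n=100,
        )
        # constant values: the histogram mode midpoint is exactly ln(1) = 0,
        # equidistant from both means
        values = np.full(100, 1.0)
        assert select_primary_component(model, values) == 0


class TestDating:
    @pytest.mark.parametrize(
        "ks,lam,expected",
        [
            (0.195, 2.1e-9, 46.43),
            (0.0157, 2.1e-9, 3.74),
            (0.0157, 1.23e-9, 6.38),
            (0.0, 2.1e-9, 0.0),
        ],
    )
    def test_known_dates(self, ks, lam, expected):
        assert round(divergence_time(ks, lam).t_mya, 2) == expected

    def test_exact_identity(self):
        d = divergence_time(0.3, 5e-9)
        assert d.t_mya == 0.3 / (2 * 5e-9) / 1e6

    def test_linear_in_ks_inverse_in_lambda(self):
        base = divergence_time(0.1, 2e-9).t_mya
        assert divergence_time(0.2, 2e-9).t_mya == pytest.approx(2 * base)
        assert divergence_time(0.1, 4e-9).t_mya == pytest.approx(base / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            divergence_time(0.1, 0.0)
        with pytest.raises(ValueError):
            divergence_time(-0.1, 1e-9)


class TestClockLRT:
    def test_equal_likelihoods(self):
        r = clock_lrt(-100.0, -100.0, df=1)
        assert r.statistic == 0.0
        assert r.p == 1.0

    def test_chi2_quantile(self):
        r = clock_lrt(-101.9205, -100.0, df=1)
        assert r.statistic == pytest.approx(3.841, abs=1e-3)
        assert r.p == pytest.approx(0.05, abs=1e-3)

    def test_nesting_violation_reported_not_clamped(self):
        with pytest.warns(UserWarning, match="nested"):
            r = clock_lrt(-100.0, -101.0, df=1)
        assert r.statistic == -2.0
        assert r.nesting_violation
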