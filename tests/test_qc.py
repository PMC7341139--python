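import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gremlite as gl
from gremlite import qc
from gremlite.io_formats import MISSING

from _oracles import (apply_relatedness_rule, hwe_enumeration,
                      naive_window_pruner)
from conftest import make_genotypes


class TestHweExactTest:
    @pytest.mark.parametrize("counts, expected", [
        ((1, 0, 1), 1.0 / 3.0),          # enumeration over n_Aa in {0, 2}
        ((25, 50, 25), 1.0),             # observed count is the mode
        ((10, 0, 0), 1.0),               # monomorphic
        ((0, 0, 10), 1.0),
        ((4, 1, 5), 0.015003572279114075),  # frozen enumeration value
    ])
    def test_frozen_enumeration_values(self, counts, expected):
        assert qc.hwe_exact_test(*counts) == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    def test_matches_enumeration_oracle(self, a, h, b):
        if a + h + b == 0:
            return
        assert qc.hwe_exact_test(a, h, b) == pytest.approx(
            hwe_enumeration(a, h, b), rel=1e-9, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            qc.hwe_exact_test(-1, 0, 1)
        with pytest.raises(ValueError):
            qc.hwe_exact_test(0, 0, 0)


class TestCallRate:
    def test_no_missing_is_noop(self, small_cohort):
        geno, _ = small_cohort
        clean = geno.subset(individuals=np.arange(geno.n_individuals))
        clean.dosages[clean.dosages == MISSING] = 1
        out = qc.filter_call_rate(clean, 0.98, 0.98)
        assert out.dosages.shape == clean.dosages.shape

    def test_single_low_call_individual_removed(self):
        d = np.ones((20, 100), dtype=np.int8)
        d[3, :5] = MISSING  # 95% call rate
        geno = make_genotypes(d)
        out = qc.filter_call_rate(geno, 0.98, 0.5)
        assert "I0003" not in out.iids
        assert out.n_individuals == 19

    def test_individual_first_ordering(self):
        """Crafted pattern where filter order changes the outcome.

        Individual 0 misses 3/10 SNPs (removed at 98%).  SNP 0 is missing
        only in individual 0: under individual-first filtering its call
        rate becomes 100% and it survives; SNP-first would remove it.
        """
        d = np.ones((10, 10), dtype=np.int8)
        d[0, [0, 1, 2]] = MISSING
        geno = make_genotypes(d)
        out = qc.filter_call_rate(geno, 0.98, 0.98)
        assert "I0000" not in out.iids
        assert "s00000" in list(out.snp_meta["snp"])
        assert out.n_snps == 10

    def test_idempotent(self, small_cohort):
        geno, _ = small_cohort
        once = qc.filter_call_rate(geno, 0.95, 0.95)
        twice = qc.filter_call_rate(once, 0.95, 0.95)
        assert np.array_equal(once.dosages, twice.dosages)

    def test_all_removed_is_error(self):
        d = np.full((4, 4), MISSING, dtype=np.int8)
        d[:, 0] = 1  # 25% call rate everywhere
        with pytest.raises(ValueError, match="all data removed"):
            qc.filter_call_rate(make_genotypes(d), 0.98, 0.98)


class TestHeterozygosity:
    def test_identical_rows_degenerate_sd(self):
        d = np.tile(np.array([0, 1, 2, 1, 0], dtype=np.int8), (6, 1))
        assert qc.heterozygosity_outliers(make_genotypes(d), 3.0) == []

    def test_gross_outliers_detected(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.3, size=(200, 500)).astype(np.int8)
        forced = [5, 17, 102]
        d[forced] = 1  # heterozygous everywhere: far beyond mean + 3 SD
        geno = make_genotypes(d)
        removed = qc.heterozygosity_outliers(geno, 3.0)
        # oracle: direct recomputation of rates
        rate = (d == 1).mean(axis=1)
        mu, sd = rate.mean(), rate.std(ddof=1)
        expected = [f"I{i:04d}" for i in np.flatnonzero(np.abs(rate - mu) > 3 * sd)]
        assert sorted(removed) == sorted(expected)
        assert {f"I{i:04d}" for i in forced} <= set(removed)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            qc.heterozygosity_outliers(make_genotypes([[1, 1]]), 3.0)


class TestLdPrune:
    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.4, size=200).astype(np.int8)
        other = rng.binomial(2, 0.4, size=(200, 3)).astype(np.int8)
        d = np.column_stack([col, col, other])
        kept = qc.ld_prune(make_genotypes(d), window=5, step=2, r2_max=0.2)
        assert ("s00000" in kept) != ("s00001" in kept)  # exactly one survives

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, size=(1000, 60)).astype(np.int8)
        kept = qc.ld_prune(make_genotypes(d), window=50, step=5, r2_max=0.2)
        assert len(kept) == 60

    @pytest.mark.parametrize("r2_max", [0.2, 0.7])
    def test_matches_naive_reference_pruner(self, r2_max):
        geno, _ = gl.simulate_genotypes(
            gl.GenoSimSpec(n=400, m=300, ld_rho=0.95, maf_range=(0.1, 0.5),
                           seed=21))
        kept = qc.ld_prune(geno, window=50, step=5, r2_max=r2_max)
        p = geno.allele1_freq()
        maf = np.minimum(p, 1 - p)
        mask = naive_window_pruner(geno.dosages, maf, 50, 5, r2_max)
        expected = list(geno.snp_meta["snp"].to_numpy()[mask])
        assert kept == expected

    def test_no_retained_window_pair_above_threshold(self):
        geno, _ = gl.simulate_genotypes(
            gl.GenoSimSpec(n=300, m=120, ld_rho=0.9, maf_range=(0.2, 0.5),
                           seed=22))
        kept = set(qc.ld_prune(geno, window=20, step=5, r2_max=0.3))
        snp_ids = geno.snp_meta["snp"].to_numpy()
        d = geno.dosages.astype(float)
        for start in range(0, geno.n_snps, 5):
            idx = [j for j in range(start, min(start + 20, geno.n_snps))
                   if snp_ids[j] in kept]
            for ii in range(len(idx)):
                for jj in range(ii + 1, len(idx)):
                    r2 = np.corrcoef(d[:, idx[ii]], d[:, idx[jj]])[0, 1] ** 2
                    assert r2 <= 0.3 + 1e-9


@pytest.fixture(scope="module")
def related_cohort():
    return gl.simulate_genotypes(
        gl.GenoSimSpec(n=60, m=2000, maf_range=(0.1, 0.5),
                       related_pairs=[("duplicate", 1),
                                      ("parent-offspring", 1)], seed=23))


class TestIbd:
    def test_duplicate_and_parent_offspring_pihat(self, related_cohort):
        geno, truth = related_cohort
        pihat = {tuple(sorted(e.pair)): e.pi_hat for e in qc.estimate_ibd(geno)}
        rels = {rel: tuple(sorted((a, b))) for a, b, rel in truth.pedigree}
        assert pihat[rels["duplicate"]] >= 0.95
        assert pihat[rels["parent-offspring"]] == pytest.approx(0.5, abs=0.05)

    def test_unrelated_pihat_near_zero(self):
        geno, _ = gl.simulate_genotypes(
            gl.GenoSimSpec(n=50, m=5000, maf_range=(0.1, 0.5), seed=24))
        ests = qc.estimate_ibd(geno)
        first = next(e for e in ests if set(e.pair) == {"I000000", "I000001"})
        assert first.pi_hat <= 0.05
        assert np.mean([e.pi_hat for e in ests]) <= 0.02

    def test_self_pair_pihat_is_one(self):
        rng = np.random.default_rng(3)
        row = rng.binomial(2, 0.4, size=1000).astype(np.int8)
        other = rng.binomial(2, 0.4, size=(2, 1000)).astype(np.int8)
        d = np.vstack([row, row, other])
        ests = qc.estimate_ibd(make_genotypes(d))
        self_pair = next(e for e in ests if set(e.pair) == {"I0000", "I0001"})
        assert self_pair.pi_hat == pytest.approx(1.0, abs=1e-6)

    def test_probabilities_form_simplex(self, related_cohort):
        geno, _ = related_cohort
        for e in qc.estimate_ibd(geno):
            assert 0 <= e.ibd0 <= 1 and 0 <= e.ibd1 <= 1 and 0 <= e.ibd2 <= 1
            assert e.ibd0 + e.ibd1 + e.ibd2 == pytest.approx(1.0)

    def test_monomorphic_only_rejected(self):
        d = np.zeros((4, 10), dtype=np.int8)
        with pytest.raises(ValueError, match="polymorphic"):
            qc.estimate_ibd(make_genotypes(d))


class TestRemoveRelated:
    @staticmethod
    def _geno_with_call_rates(rates, m=200):
        d = np.ones((len(rates), m), dtype=np.int8)
        for i, r in enumerate(rates):
            d[i, :round((1 - r) * m)] = MISSING
        return make_genotypes(d, iids=list("ABCDEFG"[:len(rates)]))

    @staticmethod
    def _pair(a, b, pihat):
        p2 = max(2 * pihat - 1.0, 0.0)
        p1 = 2 * (pihat - p2)
        return qc.RelatednessEstimate((a, b), 1.0 - p1 - p2, p1, p2)

    def test_below_threshold_keeps_everyone(self):
        geno = self._geno_with_call_rates([1.0, 1.0])
        assert qc.remove_related([self._pair("A", "B", 0.1)], geno, 0.2) == []

    def test_lower_call_rate_member_removed(self):
        geno = self._geno_with_call_rates([0.99, 0.995])
        removed = qc.remove_related([self._pair("A", "B", 0.9)], geno, 0.2)
        assert removed == ["A"]

    def test_tie_removes_later_listed(self):
        geno = self._geno_with_call_rates([1.0, 1.0])
        removed = qc.remove_related([self._pair("A", "B", 0.9)], geno, 0.2)
        assert removed == ["B"]

    def test_chain_matches_exhaustive_rule(self):
        """A-B and B-C related; call rates A > B > C."""
        geno = self._geno_with_call_rates([0.99, 0.98, 0.97])
        pairs = [self._pair("A", "B", 0.6), self._pair("B", "C", 0.6)]
        removed = qc.remove_related(pairs, geno, 0.2)
        call = dict(zip(geno.iids, geno.call_rates()))
        expected = apply_relatedness_rule(
            [(("A", "B"), 0.6), (("B", "C"), 0.6)], call)
        assert removed == expected == ["B"]


class TestFullChain:
    def test_report_counts_telescope(self):
        geno, _ = gl.simulate_genotypes(
            gl.GenoSimSpec(n=80, m=400, maf_range=(0.05, 0.5),
                           missing_rate=0.02,
                           related_pairs=[("duplicate", 2)], seed=25))
        final, pruned_ids, report = qc.run_qc(geno)
        df = report.to_frame()
        for prev, nxt in zip(df.index[:-1], df.index[1:]):
            assert df.loc[nxt, "n_ind_in"] == df.loc[prev, "n_ind_out"]
            assert df.loc[nxt, "n_snp_in"] == df.loc[prev, "n_snp_out"]
        assert df["ind_removed"].sum() == geno.n_individuals - final.n_individuals
        assert final.n_snps == df.iloc[-1]["n_snp_out"]
        # duplicates must be gone
        assert df["ind_removed"].sum() >= 2
        assert set(pruned_ids) <= set(geno.snp_meta["snp"])
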