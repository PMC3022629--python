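"""Association engine tests against an independent normal-equations oracle.

The oracle fits y on [1 | X] via statsmodels OLS and takes the Wald t /
joint F p-values from its reference distributions, entirely separate from
the package's own closed-form path.
"""

import math

import numpy as np
import pytest
import statsmodels.api as sm

import eqtlscan as eq
from eqtlscan.assoc import GENOTYPE_CLASSES, P_FLOOR

MODELS = ["additive", "dominant", "recessive", "genotypic"]


def ols_oracle(columns, y):
    """statsmodels OLS fit: (beta_add, se_add, stat, p) for the genotype term(s)."""
    X = sm.add_constant(np.column_stack(columns))
    fit = sm.OLS(y, X).fit()
    if len(columns) == 1:
        return fit.params[1], fit.bse[1], fit.tvalues[1], fit.pvalues[1]
    # joint F for both genotype terms
    r = np.zeros((2, 3))
    r[0, 1] = r[1, 2] = 1.0
    ftest = fit.f_test(r)
    return fit.params[1], fit.bse[1], float(ftest.fvalue), float(ftest.pvalue)


def random_calls(rng, n, maf=0.3, alleles=("A", "G")):
    counts = rng.binomial(2, maf, size=n)
    calls = np.empty((n, 2), dtype="U8")
    calls[:, 0] = np.where(counts >= 1, alleles[0], alleles[1])
    calls[:, 1] = np.where(counts == 2, alleles[0], alleles[1])
    return calls, counts


class TestCodeGenotypes:
    CALLS = np.array(
        [["A", "A"], ["A", "G"], ["G", "G"], ["A", "G"], ["G", "G"], ["G", "G"]],
        dtype="U8",
    )  # A count 4/12 -> A is minor

    def test_additive_counts_minor_alleles(self):
        d = eq.code_genotypes(self.CALLS, "additive")
        assert d.minor_allele == "A" and d.major_allele == "G"
        assert d.columns[0].tolist() == [2, 1, 0, 1, 0, 0]

    def test_dominant_carrier_indicator(self):
        d = eq.code_genotypes(self.CALLS, "dominant")
        assert d.columns[0].tolist() == [1, 1, 0, 1, 0, 0]

    def test_recessive_homozygote_indicator(self):
        d = eq.code_genotypes(self.CALLS, "recessive")
        assert d.columns[0].tolist() == [1, 0, 0, 0, 0, 0]

    def test_genotypic_two_columns(self):
        d = eq.code_genotypes(self.CALLS, "genotypic")
        assert d.columns[0].tolist() == [2, 1, 0, 1, 0, 0]
        assert d.columns[1].tolist() == [0, 1, 0, 1, 0, 0]

    def test_missing_excluded_via_kept_index(self):
        calls = self.CALLS.copy()
        calls[2] = "0"
        d = eq.code_genotypes(calls, "additive")
        assert d.kept_index.tolist() == [0, 1, 3, 4, 5]
        assert d.n_used == 5

    def test_monomorphic_is_degenerate_not_error(self):
        calls = np.full((5, 2), "G", dtype="U8")
        d = eq.code_genotypes(calls, "additive")
        assert d.degenerate and d.minor_allele is None

    def test_three_alleles_is_data_error(self):
        calls = np.array([["A", "G"], ["C", "G"]], dtype="U8")
        with pytest.raises(eq.DataError):
            eq.code_genotypes(calls, "additive")

    def test_tie_breaks_alphabetically_and_matches_brute_count(self):
        """50/50 frequency: minor = alphabetically first; otherwise the less
        frequent allele, verified against an exhaustive count."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            calls = rng.choice(["C", "T"], size=(n, 2)).astype("U8")
            d = eq.code_genotypes(calls, "additive")
            c = (calls == "C").sum()
            t = (calls == "T").sum()
            if c == 0 or t == 0:
                assert d.degenerate
                continue
            if d.degenerate:
                # constant coding (e.g. everyone heterozygous): no variance
                continue
            expected_minor = "C" if c < t else ("T" if t < c else "C")
            assert d.minor_allele == expected_minor
            assert d.columns[0].tolist() == (
                (calls == expected_minor).sum(axis=1).astype(float).tolist()
            )

    def test_maf_over_used_samples(self):
        calls = self.CALLS.copy()
        calls[0] = "0"  # drop the AA sample: 2 A in 10 alleles
        d = eq.code_genotypes(calls, "additive")
        assert d.maf == pytest.approx(0.2)


class TestFitWald:
    def test_exact_linear_fit_hits_p_floor(self):
        calls = TestCodeGenotypes.CALLS
        d = eq.code_genotypes(calls, "additive")
        y = 2.0 * d.columns[0] + 1.0
        fit = eq.fit_wald(d, y)
        assert fit.beta == pytest.approx(2.0)
        assert fit.se == 0.0
        assert fit.p == P_FLOOR

    @pytest.mark.parametrize("model", MODELS)
    def test_oracle_equivalence_100_instances(self, model):
        """beta/se/statistic/p match the statsmodels oracle to 1e-8."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 100:
            n = int(rng.integers(20, 80))
            calls, _ = random_calls(rng, n, maf=float(rng.uniform(0.15, 0.5)))
            d = eq.code_genotypes(calls, model)
            if d.degenerate:
                continue
            y = rng.normal(size=n)
            fit = eq.fit_wald(d, y)
            b, se, stat, p = ols_oracle(d.columns, y[d.kept_index])
            assert fit.beta == pytest.approx(b, abs=1e-8)
            assert fit.se == pytest.approx(se, abs=1e-8)
            assert fit.statistic == pytest.approx(stat, abs=1e-8)
            assert fit.p == pytest.approx(p, abs=1e-8)
            checked += 1

    def test_p_matches_t_cdf_to_1e10(self):
        """Balanced 0/1/2 coding, gaussian noise: p equals the oracle t tail."""
        rng = np.random.default_rng(8)
        calls = np.array(
            [["G", "G"]] * 3 + [["A", "G"]] * 3 + [["A", "A"]] * 2, dtype="U8"
        )
        d = eq.code_genotypes(calls, "additive")
        y = rng.standard_normal(8)
        fit = eq.fit_wald(d, y)
        _, _, t_or, p_or = ols_oracle(d.columns, y)
        assert fit.p == pytest.approx(p_or, abs=1e-10)
        assert fit.df == (1, 6)

    def test_allele_relabel_invariance(self):
        """Renaming allele symbols leaves |stat| and p unchanged; swapping
        which allele is minor flips the additive beta's sign."""
        rng = np.random.default_rng(3)
        calls, counts = random_calls(rng, 60, maf=0.3, alleles=("A", "G"))
        y = rng.normal(size=60) + 0.4 * counts
        relabeled = np.where(calls == "A", "T", "C").astype("U8")
        f1 = eq.fit_wald(eq.code_genotypes(calls, "additive"), y)
        f2 = eq.fit_wald(eq.code_genotypes(relabeled, "additive"), y)
        assert abs(f1.statistic) == pytest.approx(abs(f2.statistic), rel=1e-12)
        assert f1.p == pytest.approx(f2.p, rel=1e-12)

    def test_minor_major_swap_flips_beta_sign(self):
        rng = np.random.default_rng(4)
        calls, counts = random_calls(rng, 60, maf=0.4)
        y = rng.normal(size=60) + 0.5 * counts
        d = eq.code_genotypes(calls, "additive")
        flipped = eq.CodedDesign(
            snp_id=d.snp_id, model=d.model,
            minor_allele=d.major_allele, major_allele=d.minor_allele,
            columns=[2.0 - d.columns[0]], kept_index=d.kept_index,
            minor_count=2.0 - d.minor_count,
        )
        f1, f2 = eq.fit_wald(d, y), eq.fit_wald(flipped, y)
        assert f1.beta == pytest.approx(-f2.beta, rel=1e-12)
        assert f1.p == pytest.approx(f2.p, rel=1e-12)

    def test_degenerate_design_gives_nan(self):
        d = eq.code_genotypes(np.full((10, 2), "A", dtype="U8"), "additive")
        fit = eq.fit_wald(d, np.arange(10.0))
        assert math.isnan(fit.p)


class TestClassSummaries:
    def test_all_het_hand_computed(self):
        calls = np.array([["A", "G"]] * 3, dtype="U8")
        counts, means, sds = eq.class_summaries(calls, [1.0, 2.0, 3.0])
        # monomorphic-by-genotype but both alleles present: all samples het
        assert counts["het"] == 3
        assert means["het"] == pytest.approx(2.0)
        assert sds["het"] == pytest.approx(1.0)

    def test_singleton_class_sd_is_na(self):
        calls = np.array([["A", "A"], ["G", "G"], ["G", "G"]], dtype="U8")
        counts, means, sds = eq.class_summaries(calls, [1.0, 2.0, 4.0])
        assert counts["homMinor"] == 1
        assert math.isnan(sds["homMinor"])
        assert means["homMinor"] == pytest.approx(1.0)

    def test_empty_class_reports_zero_and_na(self):
        calls = np.array([["A", "G"], ["G", "G"]], dtype="U8")
        counts, means, sds = eq.class_summaries(calls, [1.0, 2.0])
        assert counts["homMinor"] == 0
        assert math.isnan(means["homMinor"])

    def test_agrees_with_groupby_oracle(self):
        rng = np.random.default_rng(7)
        calls, counts012 = random_calls(rng, 80, maf=0.35)
        y = rng.normal(size=80)
        counts, means, sds = eq.class_summaries(calls, y)
        import pandas as pd

        df = pd.DataFrame({"g": counts012, "y": y})
        label = {0: "homMajor", 1: "het", 2: "homMinor"}
        grouped = df.groupby("g")["y"]
        for g, cls in label.items():
            if g in grouped.groups:
                assert counts[cls] == len(grouped.get_group(g))
                assert means[cls] == pytest.approx(grouped.mean()[g])
                if counts[cls] > 1:
                    assert sds[cls] == pytest.approx(grouped.std()[g])


class TestRunAssociation:
    def test_causal_snp_attains_min_p(self):
        cfg = eq.SimConfig(
            populations=[eq.PopulationSpec("CEU", n_unrelated=200)],
            snps=eq.snp_grid(21),
            causal=eq.CausalSpec("rs7", beta=1.0, noise_sd=0.5),
            seed=99,
        )
        ds = eq.simulate_genotypes(cfg)
        profile = eq.simulate_expression(ds, cfg)[0]
        mds, mp = eq.merge_samples(ds, profile)
        res = eq.run_association(mds, mp, "additive")
        best = min((r for r in res if not r.is_degenerate), key=lambda r: r.p)
        assert best.snp_id == "rs7"

    def test_all_missing_snp_gives_na_row(self, tiny_ds):
        ds = tiny_ds
        ds.calls[:, 1, :] = "0"
        mp = eq.MergedPhenotype(ds.sample_ids, [1.0, 2.0, 3.0])
        res = eq.run_association(ds, mp, "additive")
        assert res[1].is_degenerate and res[1].n_used == 0

    def test_duplicate_snp_column_identical_results(self):
        cfg = eq.SimConfig(
            populations=[eq.PopulationSpec("CEU", n_unrelated=50)],
            snps=eq.snp_grid(1),
            seed=12,
        )
        ds = eq.simulate_genotypes(cfg)
        from dataclasses import replace

        ds2 = eq.GenotypeDataset(
            samples=ds.samples,
            snps=ds.snps + [replace(ds.snps[0], snp_id="rs_dup", position_bp=999_999)],
            calls=np.concatenate([ds.calls, ds.calls], axis=1),
        )
        rng = np.random.default_rng(0)
        mp = eq.MergedPhenotype(ds2.sample_ids, rng.normal(size=50).tolist())
        r1, r2 = eq.run_association(ds2, mp, "dominant")
        assert (r1.beta, r1.se, r1.statistic, r1.p) == (r2.beta, r2.se, r2.statistic, r2.p)

    def test_per_snp_complete_cases(self):
        """A missing call at one SNP must not shrink n at other SNPs."""
        cfg = eq.SimConfig(
            populations=[eq.PopulationSpec("CEU", n_unrelated=40)],
            snps=eq.snp_grid(3),
            seed=2,
        )
        ds = eq.simulate_genotypes(cfg)
        ds.calls[0, 0, :] = "0"
        rng = np.random.default_rng(1)
        mp = eq.MergedPhenotype(ds.sample_ids, rng.normal(size=40).tolist())
        res = eq.run_association(ds, mp, "additive")
        assert res[0].n_used == 39
        assert res[1].n_used == 40 and res[2].n_used == 40

    def test_class_counts_conservation(self):
        cfg = eq.SimConfig(
            populations=[eq.PopulationSpec("CEU", n_unrelated=60)],
            snps=eq.snp_grid(5),
            missing_rate=0.1,
            seed=21,
        )
        ds = eq.simulate_genotypes(cfg)
        rng = np.random.default_rng(2)
        mp = eq.MergedPhenotype(ds.sample_ids, rng.normal(size=60).tolist())
        for j, r in enumerate(eq.run_association(ds, mp, "additive")):
            n_missing = int((ds.snp_calls(j) == "0").all(axis=1).sum())
            assert sum(r.class_counts.values()) + n_missing == 60
            assert sum(r.class_counts.values()) == r.n_used
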