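"""Paired statistics: Wilcoxon, pseudomedian, migration, cross-checks."""

import numpy as np
import pandas as pd
import pytest

from imputefilter.compare_stats import (
    bin_count_summary,
    bin_migration_matrix,
    build_paired_table,
    dbsnp_crosscheck,
    detect_dual_imputation,
    hodges_lehmann_pseudomedian,
    per_bin_tests,
    significance_stars,
    spearman_corr,
    wilcoxon_signed_rank,
    STAR_SCHEME_ONE_SIDED,
)
from imputefilter.io_formats import VariantClass, VariantRecord
from imputefilter.metrics import MAF_BIN_LABELS, classify_maf_bin


def make_run(mafs, infos=None, prefix="v", source="imputed_only"):
    mafs = np.asarray(mafs, dtype=float)
    n = mafs.size
    infos = np.ones(n) if infos is None else np.asarray(infos, dtype=float)
    df = pd.DataFrame({
        "id": [f"{prefix}{i}" for i in range(n)],
        "chrom": "20", "pos": np.arange(1, n + 1) * 10,
        "allele_a": "A", "allele_b": "G", "variant_class": "snp",
        "source": source, "maf": mafs, "minor_allele": "G", "info": infos,
    })
    df["key"] = [("20", int(p), ("A", "G")) for p in df["pos"]]
    df["bin"] = classify_maf_bin(mafs)
    return df


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        res = wilcoxon_signed_rank(x, x)
        assert res.p_value == 1.0 and res.method == "degenerate"
        assert res.n_zero == 3

    def test_three_positive_differences(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2, 3]), np.zeros(3))
        assert res.p_value == pytest.approx(0.25)
        assert res.statistic == 6.0
        assert res.method == "exact"

    def test_one_sided_direction(self):
        x, y = np.array([1.0, 2, 3, 4]), np.zeros(4)
        res_gt = wilcoxon_signed_rank(x, y, "greater")
        res_lt = wilcoxon_signed_rank(x, y, "less")
        assert res_gt.p_value < 0.1 < res_lt.p_value

    def test_exact_and_approx_agree_at_boundary(self, rng):
        # around the exact/approximate switchover the two computations
        # should agree closely
        d = rng.normal(size=25)
        d = np.sign(d) * (np.abs(d) + np.linspace(0, 1, 25))  # tie-free
        from scipy import stats as sps
        p_exact = sps.wilcoxon(d, method="exact").pvalue
        p_approx = sps.wilcoxon(d, method="approx", correction=True).pvalue
        assert abs(p_exact - p_approx) < 0.01
        assert wilcoxon_signed_rank(d, np.zeros(25)).method == "exact"
        assert wilcoxon_signed_rank(np.concatenate([d, [0.5]]),
                                    np.zeros(26)).method == "approx"

    def test_ties_force_approximation(self):
        x = np.array([1.0, 1.0, 2.0, -1.0])
        res = wilcoxon_signed_rank(x, np.zeros(4))
        assert res.method == "approx"


class TestPseudomedian:
    def test_single_value(self):
        assert hodges_lehmann_pseudomedian(np.array([5.0])) == 5.0

    def test_walsh_set(self):
        assert hodges_lehmann_pseudomedian(np.array([1.0, 2, 3])) == 2.0

    def test_symmetric_sample_centred_at_zero(self):
        d = np.array([-3.0, -1, 1, 3])
        assert hodges_lehmann_pseudomedian(d) == 0.0

    def test_translation_equivariance(self, rng):
        d = rng.normal(size=31)
        hl = hodges_lehmann_pseudomedian(d)
        assert hodges_lehmann_pseudomedian(d + 2.5) == pytest.approx(hl + 2.5)


class TestSpearman:
    def test_monotone_transform(self, rng):
        a = rng.normal(size=30)
        assert spearman_corr(a, np.exp(a)) == pytest.approx(1.0)

    def test_reversal(self, rng):
        a = rng.normal(size=30)
        assert spearman_corr(a, -a) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert spearman_corr(np.array([1, 2, 3, 4]),
                             np.array([1, 3, 2, 4])) == pytest.approx(0.8)

    def test_constant_vector_undefined(self):
        with pytest.raises(ValueError):
            spearman_corr(np.ones(5), np.arange(5.0))


class TestPairedTable:
    def test_identical_runs(self):
        run = make_run([0.1, 0.01, 0.3])
        paired = build_paired_table(run, run.copy())
        assert paired.n_pairs == 3
        assert (paired.table["maf_noqc"] == paired.table["maf_qc"]).all()
        assert paired.n_allele_discordant == 0
        assert len(paired.only_in_noqc) == len(paired.only_in_qc) == 0

    def test_disjoint_runs(self):
        a = make_run([0.1, 0.2], prefix="a")
        b = make_run([0.1, 0.2], prefix="b")
        b["pos"] += 1000
        b["key"] = [("20", int(p), ("A", "G")) for p in b["pos"]]
        paired = build_paired_table(a, b)
        assert paired.n_pairs == 0
        assert len(paired.only_in_noqc) == 2 and len(paired.only_in_qc) == 2

    def test_duplicate_keys_rejected(self):
        run = make_run([0.1, 0.2])
        dup = pd.concat([run, run.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            build_paired_table(dup, run)

    def test_join_cardinality(self, rng):
        a = make_run(rng.uniform(0, 0.5, 30))
        b = a.iloc[5:].copy()
        paired = build_paired_table(a, b)
        assert paired.n_pairs == 25
        assert len(paired.only_in_noqc) == 5

    def test_allele_discordance_flag(self):
        a = make_run([0.1, 0.2])
        b = a.copy()
        b.loc[0, "minor_allele"] = "A"
        paired = build_paired_table(a, b)
        assert paired.n_allele_discordant == 1


class TestPerBinTests:
    def test_identical_arms_degenerate(self, rng):
        run = make_run(rng.uniform(0, 0.5, 40))
        paired = build_paired_table(run, run.copy())
        out = per_bin_tests(paired, "maf")
        populated = out[out["n"] >= 2]
        assert (populated["p_two_sided"] == 1.0).all()
        assert (populated["pseudomedian"].fillna(0) == 0).all()

    def test_shift_detected_one_sided(self, rng):
        infos = rng.uniform(0.3, 0.9, 60)
        a = make_run(rng.uniform(0.11, 0.49, 60), infos + 0.05)
        b = a.copy()
        b["info"] = infos
        paired = build_paired_table(a, b)
        out = per_bin_tests(paired, "info")
        row = out[out["bin"] == "high"].iloc[0]
        assert row["p_one_sided_greater"] < 0.05
        assert row["pseudomedian"] > 0

    def test_bin_counts_partition_table(self, rng):
        run = make_run(rng.uniform(0, 0.5, 80))
        paired = build_paired_table(run, run.copy())
        out = per_bin_tests(paired, "maf")
        assert out[out["bin"] != "all"]["n"].sum() == 80
        assert out[out["bin"] == "all"]["n"].iloc[0] == 80


class TestMigration:
    def test_identical_arms_diagonal(self, rng):
        run = make_run(rng.uniform(0, 0.5, 50))
        counts, _ = bin_migration_matrix(build_paired_table(run, run.copy()))
        off_diag = counts.to_numpy().sum() - np.trace(counts.to_numpy())
        assert off_diag == 0

    def test_monomorphic_migration_percentages(self):
        """3292 null-class variants whose re-imputed classes split
        2717 / 526 / 46 / 3 give row percentages 82.5 / 16.0 / 1.4 / 0.1."""
        n = 3292
        maf_noqc = np.zeros(n)
        maf_qc = np.concatenate([
            np.zeros(2717),
            np.full(526, 3e-4),   # very rare I
            np.full(46, 7e-4),    # very rare II
            np.full(3, 2e-3),     # rare I
        ])
        a = make_run(maf_noqc)
        b = a.copy()
        b["maf"] = maf_qc
        b["bin"] = classify_maf_bin(maf_qc)
        paired = build_paired_table(a, b)
        counts, pct = bin_migration_matrix(paired)
        assert counts.loc["null", "null"] == 2717
        assert pct.loc["null", "null"] == 82.5
        assert pct.loc["null", "very_rare_I"] == 16.0
        assert pct.loc["null", "very_rare_II"] == 1.4
        assert pct.loc["null", "rare_I"] == 0.1

    def test_total_preserved(self, rng):
        a = make_run(rng.uniform(0, 0.5, 70))
        b = a.copy()
        b["maf"] = np.clip(b["maf"] * rng.uniform(0.5, 1.5, 70), 0, 0.5)
        b["bin"] = classify_maf_bin(b["maf"].to_numpy())
        paired = build_paired_table(a, b)
        counts, _ = bin_migration_matrix(paired)
        assert counts.to_numpy().sum() == 70
        # marginals match per-arm bin counts
        noqc_counts = paired.table["bin_noqc"].value_counts()
        for lab in MAF_BIN_LABELS:
            assert counts.loc[lab].sum() == noqc_counts.get(lab, 0)


class TestCrosscheck:
    def test_all_concordant(self, rng):
        run = make_run(rng.uniform(0.01, 0.5, 20))
        table = {row["id"]: (row["minor_allele"], row["maf"])
                 for _, row in run.iterrows()}
        out, summary = dbsnp_crosscheck(run, table)
        assert (out["status"] == "concordant").all()
        assert summary["spearman_concordant"] == pytest.approx(1.0)

    def test_status_partition(self):
        run = make_run([0.0, 0.1, 0.2, 0.3, 0.4])
        table = {
            "v0": ("G", 0.0),   # null_both
            "v1": ("G", 0.0),   # null_in_db
            "v2": ("A", 0.2),   # allele_discordant
            "v3": ("G", 0.3),   # concordant
            # v4 absent
        }
        out, summary = dbsnp_crosscheck(run, table)
        assert list(out["status"]) == [
            "null_both", "null_in_db", "allele_discordant", "concordant", "absent"]
        assert summary["counts"] == {k: 1 for k in out["status"]}

    def test_synthetic_injections_recovered(self, small_bundle):
        """Status counts on the generator's own MAF table match the
        injected flaw bookkeeping exactly for absent/null records."""
        from imputefilter.ls_imputer import LSParams, impute_cohort
        from imputefilter.metrics import variant_quality_table

        b = small_bundle
        study = b.study_truth_haplotypes.haplotypes[:, b.typed_site_index]
        gp = impute_cohort(study, b.typed_site_index, b.reference_panel, LSParams())
        run = variant_quality_table(gp)
        out, summary = dbsnp_crosscheck(run, b.external_maf_table)
        counts = summary["counts"]
        flaws = b.maf_table_injections
        assert counts.get("absent", 0) == len(flaws["absent"])
        status_of = dict(zip(out["id"], out["status"]))
        for vid in flaws["null"]:  # records nulled in the table
            assert status_of[vid] in ("null_in_db", "null_both")


class TestDualImputation:
    def _rec(self, pos, alleles=("A", "G"), cls=VariantClass.SNP, vid="x"):
        return VariantRecord(id=vid, chrom="20", pos=pos,
                             allele_a=alleles[0], allele_b=alleles[1],
                             variant_class=cls)

    def test_no_shared_positions(self):
        assert detect_dual_imputation([self._rec(1), self._rec(2)]) == []

    def test_snp_structural_pair(self):
        recs = [self._rec(5, vid="snp"),
                self._rec(5, alleles=("A", "AGGT"),
                          cls=VariantClass.STRUCTURAL, vid="sv")]
        pairs = detect_dual_imputation(recs)
        assert len(pairs) == 1
        involved = {r.id for p in pairs for r in p}
        assert involved == {"snp", "sv"}  # one dual imputation = two records

    def test_three_records_give_three_pairs(self):
        recs = [self._rec(5, ("A", "G"), vid="a"),
                self._rec(5, ("A", "T"), vid="b"),
                self._rec(5, ("A", "AGG"), cls=VariantClass.STRUCTURAL, vid="c")]
        assert len(detect_dual_imputation(recs)) == 3


class TestBinCountSummary:
    def test_percentages_use_stated_denominator(self):
        counts = dict(zip(MAF_BIN_LABELS, [10, 10, 10, 10, 10, 20, 20, 10]))
        s = bin_count_summary(counts)
        assert s["total"] == 100
        assert s["pct_below_001_incl_null"] == pytest.approx(50.0)
        assert s["pct_below_001_excl_null"] == pytest.approx(40.0)
        assert s["pct_by_class"]["very_rare"] == pytest.approx(20.0)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=40),
       st.floats(-50, 50, allow_nan=False))
def test_pseudomedian_translation_equivariant(d, c):
    d = np.asarray(d)
    assert hodges_lehmann_pseudomedian(d + c) == pytest.approx(
        hodges_lehmann_pseudomedian(d) + c, abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(0.01, 100, allow_nan=False), min_size=1, max_size=20))
def test_wilcoxon_all_positive_differences_small_p_one_sided(d):
    d = np.asarray(d)
    res = wilcoxon_signed_rank(d, np.zeros_like(d), "greater")
    # W+ maximal: the one-sided p equals the point mass of the top value
    assert 0 < res.p_value <= 0.5
    assert res.statistic == res.n_nonzero * (res.n_nonzero + 1) / 2


def test_significance_star_schemes():
    assert significance_stars(2e-5) == "****"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""
    assert significance_stars(3e-4, STAR_SCHEME_ONE_SIDED) == "***"
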