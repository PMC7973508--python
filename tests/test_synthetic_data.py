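"""Generator contracts: determinism, spectrum, LD, corruption."""

import numpy as np
import pytest

from imputefilter.qc_prefilter import hwe_exact_test
from imputefilter.synthetic_data import (
    SimulationConfig,
    build_external_maf_table,
    generate_haplotype_pool,
    generate_study_cohort,
    inject_errors,
    select_typed_sites,
    simulate_truth_bundle,
)
from imputefilter.io_formats import MISSING

from conftest import small_sim_config


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_founders=1),
        dict(n_typed=500, n_sites=400),
        dict(missing_rate=1.5),
        dict(genotype_error_rate=-0.1),
        dict(region_length_bp=0),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            small_sim_config(**kwargs)

    def test_default_seed_is_fixed(self):
        assert SimulationConfig().seed == 1411139299


class TestHaplotypePool:
    def test_no_recomb_no_mutation_copies_founders(self):
        cfg = small_sim_config(n_founders=2, n_ref_haplotypes=30,
                               recomb_rate_per_bp=0.0, mutation_rate_per_site=0.0)
        panel = generate_haplotype_pool(cfg)
        founders = panel.haplotypes[:2]
        for hap in panel.haplotypes:
            assert any(np.array_equal(hap, f) for f in founders)

    def test_panel_density_matches_region(self):
        cfg = SimulationConfig(n_ref_haplotypes=20, n_founders=20,
                               n_study=2, n_sites=27_090, n_typed=100,
                               region_length_bp=2_000_000)
        panel = generate_haplotype_pool(cfg)
        density_per_kb = panel.n_sites / (cfg.region_length_bp / 1000)
        assert density_per_kb == pytest.approx(13.545)
        assert panel.positions.size == 27_090
        assert np.all(np.diff(panel.positions) > 0)

    def test_determinism_bit_identical(self):
        cfg = small_sim_config()
        p1 = generate_haplotype_pool(cfg)
        p2 = generate_haplotype_pool(cfg)
        assert np.array_equal(p1.haplotypes, p2.haplotypes)
        assert np.array_equal(p1.positions, p2.positions)

    def test_frequency_spectrum_decreasing(self):
        # 1/f spectrum: equal-width MAF histogram counts fall with MAF
        cfg = SimulationConfig(n_ref_haplotypes=200, n_founders=200, n_study=2,
                               n_sites=12_000, n_typed=10,
                               region_length_bp=1_000_000, seed=3)
        panel = generate_haplotype_pool(cfg)
        maf = panel.maf()
        counts, _ = np.histogram(maf[maf > 0], bins=10, range=(0.0, 0.5))
        from scipy.stats import spearmanr
        rho = spearmanr(np.arange(10), counts).statistic
        assert rho < -0.9

    def test_ld_decays_with_distance(self, small_bundle):
        panel = small_bundle.reference_panel
        h = panel.haplotypes.astype(float)
        maf = panel.maf()
        poly = np.flatnonzero((maf > 0.05))
        pos = panel.positions[poly]
        hp = h[:, poly]

        def corr(i, j):
            return abs(np.corrcoef(hp[:, i], hp[:, j])[0, 1])

        adjacent = [corr(i, i + 1) for i in range(len(poly) - 1)]
        far_pairs = [(i, j) for i in range(len(poly))
                     for j in range(i + 1, len(poly))
                     if pos[j] - pos[i] >= 20_000][:200]
        far = [corr(i, j) for i, j in far_pairs]
        assert np.mean(adjacent) > np.mean(far)


class TestStudyCohort:
    def test_no_recomb_no_mutation_equals_reference_member(self):
        cfg = small_sim_config(recomb_rate_per_bp=0.0, mutation_rate_per_site=0.0)
        panel = generate_haplotype_pool(cfg)
        cohort = generate_study_cohort(panel, cfg)
        ref_set = {h.tobytes() for h in panel.haplotypes}
        for hap in cohort.haplotypes:
            assert hap.tobytes() in ref_set

    def test_haplotype_count_is_twice_individuals(self, default_bundle):
        cfg = default_bundle.config
        assert cfg.n_study == 1031
        assert default_bundle.study_truth_haplotypes.n_haplotypes == 2062

    def test_reproducible(self):
        cfg = small_sim_config()
        panel = generate_haplotype_pool(cfg)
        c1 = generate_study_cohort(panel, cfg)
        c2 = generate_study_cohort(panel, cfg)
        assert np.array_equal(c1.haplotypes, c2.haplotypes)


class TestTypedSites:
    def test_all_sites_typed_when_counts_match(self):
        cfg = small_sim_config(n_typed=400, n_sites=400)
        panel = generate_haplotype_pool(cfg)
        assert np.array_equal(select_typed_sites(panel, cfg), np.arange(400))

    def test_typed_sites_skew_common(self, default_bundle):
        panel = default_bundle.reference_panel
        typed = default_bundle.typed_site_index
        maf = panel.maf()
        untyped = np.setdiff1d(np.arange(panel.n_sites), typed)
        assert maf[typed].mean() > maf[untyped].mean()

    def test_typed_fraction_emulates_array_content(self, default_bundle):
        cfg = default_bundle.config
        frac = cfg.n_typed / cfg.n_sites
        assert frac == pytest.approx(1762 / 27_090, rel=0.05)


class TestInjectErrors:
    def test_zero_rates_reproduce_truth(self):
        cfg = small_sim_config(genotype_error_rate=0.0, missing_rate=0.0,
                               bad_site_fraction=0.0)
        panel = generate_haplotype_pool(cfg)
        cohort = generate_study_cohort(panel, cfg)
        typed = select_typed_sites(panel, cfg)
        gm, bad = inject_errors(cohort, typed, cfg)
        h = cohort.haplotypes[:, typed]
        truth = (h[0::2] + h[1::2]).T
        assert np.array_equal(gm.genotypes, truth)
        assert bad.size == 0

    def test_full_missingness(self):
        cfg = small_sim_config(missing_rate=1.0)
        panel = generate_haplotype_pool(cfg)
        cohort = generate_study_cohort(panel, cfg)
        typed = select_typed_sites(panel, cfg)
        gm, _ = inject_errors(cohort, typed, cfg)
        assert np.all(gm.genotypes == MISSING)

    def test_bad_sites_depress_hwe_p(self):
        # heterozygote-excess corruption at bad sites should push their
        # exact-test p-values below those of clean sites, in distribution
        cfg = small_sim_config(n_sites=600, n_typed=300, n_study=300,
                               bad_site_fraction=0.25, genotype_error_rate=0.02)
        panel = generate_haplotype_pool(cfg)
        cohort = generate_study_cohort(panel, cfg)
        typed = select_typed_sites(panel, cfg)
        gm, bad_pos = inject_errors(cohort, typed, cfg)
        assert bad_pos.size >= 50
        is_bad = np.isin(gm.positions, bad_pos)

        def hwe_for(i):
            g = gm.genotypes[i]
            g = g[g != MISSING]
            return hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()),
                                  int((g == 2).sum()))

        p_bad = [hwe_for(i) for i in np.flatnonzero(is_bad)]
        p_clean = [hwe_for(i) for i in np.flatnonzero(~is_bad)]
        assert np.median(p_bad) < np.median(p_clean)

    def test_truth_haplotypes_untouched(self):
        cfg = small_sim_config()
        panel = generate_haplotype_pool(cfg)
        cohort = generate_study_cohort(panel, cfg)
        before = cohort.haplotypes.copy()
        typed = select_typed_sites(panel, cfg)
        inject_errors(cohort, typed, cfg)
        assert np.array_equal(cohort.haplotypes, before)


class TestBundle:
    def test_bundle_determinism(self):
        cfg = small_sim_config()
        b1 = simulate_truth_bundle(cfg)
        b2 = simulate_truth_bundle(cfg)
        assert np.array_equal(b1.observed_genotypes.genotypes,
                              b2.observed_genotypes.genotypes)
        assert b1.external_maf_table == b2.external_maf_table

    def test_maf_table_injection_bookkeeping(self, small_bundle):
        table = small_bundle.external_maf_table
        flaws = small_bundle.maf_table_injections
        for vid in flaws["null"]:
            assert table[vid][1] == 0.0
        for vid in flaws["absent"]:
            assert vid not in table
        panel = small_bundle.reference_panel
        minor_truth = {}
        f = panel.allele_freq()
        for i in range(panel.n_sites):
            minor_truth[str(panel.ids[i])] = (
                str(panel.allele_b[i]) if f[i] <= 0.5 else str(panel.allele_a[i]))
        for vid in flaws["discordant"]:
            assert table[vid][0] != minor_truth[vid]

    def test_held_out_typed_sites_missing_from_reference(self):
        cfg = small_sim_config(n_typed_not_in_reference=5)
        b = simulate_truth_bundle(cfg)
        typed_pos = set(b.typed_positions.tolist())
        ref_pos = set(b.reference_panel.positions.tolist())
        assert len(typed_pos - ref_pos) == 5

    def test_observed_only_at_typed_sites(self, small_bundle):
        assert (small_bundle.observed_genotypes.n_variants
                == small_bundle.typed_site_index.size)
        assert small_bundle.study_truth_haplotypes.n_sites \
            == small_bundle.config.n_sites


def test_maf_table_build_covers_panel(small_bundle):
    cfg = small_bundle.config
    table, flaws = build_external_maf_table(small_bundle.reference_panel, cfg)
    n_absent = len(flaws["absent"])
    assert len(table) + n_absent == small_bundle.reference_panel.n_sites
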