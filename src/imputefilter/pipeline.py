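"""End-to-end paired experiment orchestration.

simulate -> (no-QC | QC) -> impute both arms with identical model
parameters and seed -> per-variant metrics -> paired statistics ->
filtration strategies -> report.  The two arms differ only in which
typed variants enter the imputer, which is exactly the variable under
study; the imputation itself is deterministic, so arm outputs are
reproducible byte-for-byte under a fixed configuration.

Masked accuracy (concordance and r2 at typed sites) uses grouped
leave-out: evaluated typed sites are split into folds, each fold is
imputed with its observations withheld, and the withheld predictions
are scored against the original calls.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from imputefilter.io_formats import MISSING, GenotypeMatrix, GenotypeProbabilities
from imputefilter import compare_stats, metrics, post_filter
from imputefilter.ls_imputer import LSParams, impute_cohort
from imputefilter.qc_prefilter import QCConfig, QCReport, apply_qc
from imputefilter.synthetic_data import SimulationConfig, TruthBundle, simulate_truth_bundle

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ArmResult",
    "ExperimentResult",
    "phase_with_truth_template",
    "match_typed_sites",
    "run_experiment",
    "build_report",
]


@dataclass
class ExperimentConfig:
    """Configuration of one paired experiment.

    Both arms share ``ls`` and the simulation seed, so the only
    difference between runs is the typed-variant set.  ``masking`` is
    the fraction of typed sites scored by grouped leave-out (1.0 = all),
    split into ``masking_folds`` folds.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    ls: LSParams = field(default_factory=LSParams)
    strategies: list[post_filter.FilterStrategy] | None = None
    masking: float = 0.3
    masking_folds: int = 2
    fb_dtype: str = "float32"  # imputation arithmetic; float64 for audits
    het_equivalents: float = 1.5
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.masking <= 1.0:
            raise ValueError("masking must lie in [0, 1]")
        if self.masking_folds < 1:
            raise ValueError("masking_folds must be >= 1")

    @property
    def seed(self) -> int:
        return self.simulation.seed


@dataclass
class ArmResult:
    """One arm (QC or no-QC) of the experiment."""

    name: str
    gp: GenotypeProbabilities
    quality: pd.DataFrame           # metrics.variant_quality_table output
    concordance: float | None
    r2_type0: pd.DataFrame          # id, pos, r2 at masked typed sites
    n_typed_used: int
    n_typed_skipped: int            # typed sites absent from the reference
    qc_report: QCReport | None = None


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    bundle: TruthBundle
    arms: dict[str, ArmResult]
    paired: compare_stats.PairedRunTable
    maf_tests: pd.DataFrame
    info_tests: pd.DataFrame
    migration_counts: pd.DataFrame
    migration_pct: pd.DataFrame
    crosscheck: pd.DataFrame
    crosscheck_summary: dict
    dual_imputations: list
    survival: dict[str, pd.DataFrame]     # per arm
    fold_changes: dict[str, dict]         # per arm
    two_step_rows: dict[str, post_filter.SurvivalRow]
    maf_min_used: float


def phase_with_truth_template(observed: GenotypeMatrix, truth_haps: np.ndarray
                              ) -> np.ndarray:
    """Resolve observed hard genotypes into haplotype alleles.

    Uses the simulator's truth phase as the template: calls that agree
    with the truth genotype inherit the true phase; discordant
    heterozygote calls get a deterministic allele order; missing calls
    yield missing alleles on both haplotypes.  Stands in for an
    external pre-phasing step, which is an input to -- not part of --
    the imputation model.

    ``truth_haps`` is (2*n_ind, n_typed); returns the same shape.
    """
    g_obs = observed.genotypes  # (n_var, n_ind)
    h1 = truth_haps[0::2].T.astype(np.int8)  # (n_var, n_ind)
    h2 = truth_haps[1::2].T.astype(np.int8)
    g_truth = h1 + h2
    out1, out2 = h1.copy(), h2.copy()
    mismatch = (g_obs != g_truth)
    out1[mismatch & (g_obs == 0)] = 0
    out2[mismatch & (g_obs == 0)] = 0
    out1[mismatch & (g_obs == 2)] = 1
    out2[mismatch & (g_obs == 2)] = 1
    het = mismatch & (g_obs == 1)
    # deterministic order for template-free heterozygotes: parity of
    # (variant index + sample index) avoids a systematic strand bias
    vi, si = np.nonzero(het)
    first_minor = (vi + si) % 2 == 0
    out1[vi, si] = np.where(first_minor, 1, 0).astype(np.int8)
    out2[vi, si] = np.where(first_minor, 0, 1).astype(np.int8)
    miss = g_obs == MISSING
    out1[miss] = MISSING
    out2[miss] = MISSING
    haps = np.empty_like(truth_haps, dtype=np.int8)
    haps[0::2] = out1.T
    haps[1::2] = out2.T
    return haps


def match_typed_sites(ref_positions: np.ndarray, typed_positions: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Map typed positions into the reference site axis.

    Returns (index into reference sites, boolean keep-mask over typed
    sites).  Typed sites absent from the reference are skipped with a
    warning -- they cannot be imputed, matching how production engines
    treat them.
    """
    pos_to_idx = {int(p): i for i, p in enumerate(ref_positions)}
    idx, keep = [], []
    for p in typed_positions:
        j = pos_to_idx.get(int(p))
        keep.append(j is not None)
        if j is not None:
            idx.append(j)
    n_skip = len(keep) - sum(keep)
    if n_skip:
        warnings.warn(f"{n_skip} typed site(s) absent from the reference panel; "
                      "skipped (not imputed)")
    return np.array(idx, dtype=int), np.array(keep, dtype=bool)


def _impute_arm(bundle: TruthBundle, observed: GenotypeMatrix,
                cfg: ExperimentConfig, name: str,
                qc_report: QCReport | None) -> ArmResult:
    ref = bundle.reference_panel
    cohort = bundle.study_truth_haplotypes
    # columns of the full typed set that survived this arm's filtering
    typed_pos = observed.positions
    full_typed_pos = cohort.positions[bundle.typed_site_index]
    col_of = {int(p): i for i, p in enumerate(full_typed_pos)}
    arm_cols = np.array([col_of[int(p)] for p in typed_pos], dtype=int)
    site_idx = bundle.typed_site_index[arm_cols]

    # QC may have dropped samples: keep truth haplotype rows aligned
    full_samples = bundle.observed_genotypes.samples
    ind_idx = np.array([full_samples.index(s) for s in observed.samples])
    hap_rows = np.ravel(np.column_stack((2 * ind_idx, 2 * ind_idx + 1)))
    truth_typed = cohort.haplotypes[hap_rows][:, site_idx]
    study_haps = phase_with_truth_template(observed, truth_typed)

    ref_idx, keep = match_typed_sites(ref.positions, typed_pos)
    study_haps = study_haps[:, keep]

    logger.info("[%s] imputing %d individuals at %d sites (%d typed, seed %d)",
                name, observed.n_samples, ref.n_sites, ref_idx.size,
                cfg.simulation.seed)
    gp = impute_cohort(study_haps, ref_idx, ref, cfg.ls,
                       samples=list(observed.samples), dtype=np.dtype(cfg.fb_dtype))
    quality = metrics.variant_quality_table(gp)

    concordance, r2_df = _masked_accuracy(
        study_haps, ref_idx, observed.subset(variant_index=np.flatnonzero(keep)),
        ref, cfg)
    return ArmResult(name=name, gp=gp, quality=quality, concordance=concordance,
                     r2_type0=r2_df, n_typed_used=int(ref_idx.size),
                     n_typed_skipped=int((~keep).sum()), qc_report=qc_report)


def _masked_accuracy(study_haps: np.ndarray, ref_idx: np.ndarray,
                     observed: GenotypeMatrix, ref, cfg: ExperimentConfig
                     ) -> tuple[float | None, pd.DataFrame]:
    """Grouped leave-out accuracy at typed sites.

    Splits the evaluated typed sites into folds; each fold is re-imputed
    with its observations withheld and its predictions scored against
    the original calls.
    """
    n_typed = ref_idx.size
    if n_typed == 0 or cfg.masking == 0.0:
        return None, pd.DataFrame(columns=["id", "pos", "r2_type0"])
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(99,)))
    n_eval = max(1, int(round(cfg.masking * n_typed)))
    eval_cols = np.sort(rng.choice(n_typed, size=n_eval, replace=False))
    folds = np.array_split(rng.permutation(eval_cols), min(cfg.masking_folds, n_eval))

    n_match, n_tot = 0, 0
    r2_rows = []
    for fold in folds:
        if fold.size == 0:
            continue
        masked = study_haps.copy()
        masked[:, fold] = MISSING
        gp = impute_cohort(masked, ref_idx, ref, cfg.ls,
                           samples=list(observed.samples),
                           dtype=np.dtype(cfg.fb_dtype))
        sub = GenotypeProbabilities(
            [gp.variants[ref_idx[c]] for c in fold], gp.samples,
            gp.probs[ref_idx[fold]])
        orig = observed.genotypes[fold]
        called = orig != MISSING
        best = np.argmax(sub.probs, axis=2)
        n_match += int((best[called] == orig[called]).sum())
        n_tot += int(called.sum())
        r2 = metrics.r2_type0_masked(sub, orig)
        for j, c in enumerate(fold):
            r2_rows.append({"id": str(observed.ids[c]),
                            "pos": int(observed.positions[c]),
                            "r2_type0": float(r2[j])})
    conc = n_match / n_tot if n_tot else None
    r2_df = pd.DataFrame(r2_rows).sort_values("pos").reset_index(drop=True) \
        if r2_rows else pd.DataFrame(columns=["id", "pos", "r2_type0"])
    return conc, r2_df


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the full paired experiment; optionally write all outputs."""
    logger.info("simulating truth bundle (seed %d)", cfg.simulation.seed)
    bundle = simulate_truth_bundle(cfg.simulation)
    observed = bundle.observed_genotypes

    filtered, qc_report = apply_qc(observed, cfg.qc)
    logger.info("QC removed %.1f%% of %d typed variants",
                100 * qc_report.fraction_removed, observed.n_variants)

    arms = {
        "noqc": _impute_arm(bundle, observed, cfg, "noqc", None),
        "qc": _impute_arm(bundle, filtered, cfg, "qc", qc_report),
    }

    paired = compare_stats.build_paired_table(arms["noqc"].quality,
                                              arms["qc"].quality)
    maf_tests = compare_stats.per_bin_tests(paired, "maf")
    info_tests = compare_stats.per_bin_tests(paired, "info")
    mig_counts, mig_pct = compare_stats.bin_migration_matrix(paired)
    crosscheck, cc_summary = compare_stats.dbsnp_crosscheck(
        arms["noqc"].quality, bundle.external_maf_table)
    duals = compare_stats.detect_dual_imputation(
        [v for v in arms["noqc"].gp.variants])

    maf_min = post_filter.het_equivalent_threshold(observed.n_samples,
                                                   cfg.het_equivalents)
    strategies = cfg.strategies or [
        post_filter.FilterStrategy(kind="none"),
        post_filter.FilterStrategy(kind="info_threshold", info_min=0.3),
        post_filter.FilterStrategy(kind="info_threshold", info_min=0.8),
        post_filter.FilterStrategy(kind="two_step", maf_min=maf_min, info_min=0.3),
    ]
    survival, fold_changes, two_step_rows = {}, {}, {}
    for name, arm in arms.items():
        survival[name] = post_filter.survival_by_bin(arm.quality, strategies)
        fold_changes[name] = post_filter.fold_change_report(arm.quality)
        two_step = next((s for s in strategies if s.kind == "two_step"), None)
        if two_step is not None:
            _, two_step_rows[name] = post_filter.apply_strategy(arm.quality, two_step)

    result = ExperimentResult(
        config=cfg, bundle=bundle, arms=arms, paired=paired,
        maf_tests=maf_tests, info_tests=info_tests,
        migration_counts=mig_counts, migration_pct=mig_pct,
        crosscheck=crosscheck, crosscheck_summary=cc_summary,
        dual_imputations=duals, survival=survival, fold_changes=fold_changes,
        two_step_rows=two_step_rows, maf_min_used=maf_min,
    )
    if cfg.output_dir:
        _write_outputs(result, Path(cfg.output_dir))
    return result


def _write_outputs(result: ExperimentResult, out: Path) -> None:
    from imputefilter.io_formats import write_gen

    out.mkdir(parents=True, exist_ok=True)
    for name, arm in result.arms.items():
        write_gen(arm.gp, out / f"imputed_{name}.gen", out / f"imputed_{name}.sample")
        arm.quality.drop(columns="key").to_csv(out / f"metrics_{name}.tsv",
                                               sep="\t", index=False)
        arm.r2_type0.to_csv(out / f"r2_type0_{name}.tsv", sep="\t", index=False)
    result.maf_tests.to_csv(out / "table_maf_tests.tsv", sep="\t", index=False)
    result.info_tests.to_csv(out / "table_info_tests.tsv", sep="\t", index=False)
    result.migration_counts.to_csv(out / "migration_counts.tsv", sep="\t")
    result.migration_pct.to_csv(out / "migration_pct.tsv", sep="\t")
    result.crosscheck.drop(columns="key").to_csv(out / "crosscheck.tsv",
                                                 sep="\t", index=False)
    for name, df in result.survival.items():
        df.to_csv(out / f"survival_{name}.tsv", sep="\t")
    md, summary = build_report(result)
    (out / "report.md").write_text(md)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default))


def _json_default(obj):
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _summary_dict(result: ExperimentResult) -> dict:
    arms = result.arms
    qc_rep = arms["qc"].qc_report
    bin_counts = {
        name: arm.quality["bin"].value_counts().reindex(
            metrics.MAF_BIN_LABELS, fill_value=0).astype(int).to_dict()
        for name, arm in arms.items()
    }
    return {
        "seed": result.config.seed,
        "n_reference_sites": int(result.bundle.reference_panel.n_sites),
        "n_imputed_variants": {n: int(a.gp.n_variants) for n, a in arms.items()},
        "n_typed_used": {n: a.n_typed_used for n, a in arms.items()},
        "qc_fraction_removed": float(qc_rep.fraction_removed) if qc_rep else None,
        "concordance": {n: a.concordance for n, a in arms.items()},
        "mean_r2_type0": {
            n: float(np.nanmean(a.r2_type0["r2_type0"]))
            if len(a.r2_type0) else None for n, a in arms.items()},
        "bin_counts": bin_counts,
        "bin_count_summary": {n: compare_stats.bin_count_summary(c)
                              for n, c in bin_counts.items()},
        "crosscheck": result.crosscheck_summary,
        "n_dual_imputations": len(result.dual_imputations),
        "maf_min_two_step": result.maf_min_used,
        "fold_changes": {n: {k: v for k, v in fc.items() if k != "per_bin"}
                         for n, fc in result.fold_changes.items()},
        "two_step": {n: asdict(r) for n, r in result.two_step_rows.items()},
    }


def build_report(result: ExperimentResult) -> tuple[str, dict]:
    """Render the Markdown report and the JSON-ready summary dict.

    The report self-checks its own arithmetic: bin counts are summed and
    compared to totals, and every percentage states its denominator.
    """
    s = _summary_dict(result)
    lines = [
        "# Paired imputation filtration report",
        "",
        f"Seed: {s['seed']} (identical in both arms)",
        f"Reference sites: {s['n_reference_sites']}; imputed variants per arm: "
        f"{s['n_imputed_variants']}",
        f"QC removed {100 * (s['qc_fraction_removed'] or 0):.1f}% of typed variants.",
        "",
        "## Masked-genotype accuracy",
    ]
    for name, c in s["concordance"].items():
        r2 = s["mean_r2_type0"][name]
        lines.append(f"- {name}: concordance {c:.4f}" +
                     (f", mean r2_type0 {r2:.4f}" if r2 is not None else "")
                     if c is not None else f"- {name}: not evaluated")
    lines += ["", "## Per-bin counts (denominator: arm total)"]
    for name, summ in s["bin_count_summary"].items():
        total = summ["total"]
        check = sum(s["bin_counts"][name].values())
        lines.append(f"- {name}: total {total} (sum check {check}); "
                     f"MAF<0.01 incl. null {summ['pct_below_001_incl_null']:.0f}%, "
                     f"excl. null {summ['pct_below_001_excl_null']:.0f}%")
    lines += ["", "## Paired MAF tests (two-sided)", result.maf_tests.to_string(index=False),
              "", "## Paired info tests (one-sided: no-QC > QC)",
              result.info_tests.to_string(index=False),
              "", "## Bin migration (row %, no-QC rows vs QC columns)",
              result.migration_pct.to_string(),
              "", "## External MAF cross-check",
              f"Status counts: {s['crosscheck']['counts']}; Spearman over "
              f"concordant records: {s['crosscheck']['spearman_concordant']}",
              "", "## Post-filtration survival"]
    for name, df in result.survival.items():
        lines += [f"### arm {name}", df.to_string(), ""]
    for name, fc in s["fold_changes"].items():
        lines.append(f"- {name}: info>0.3 vs info>0.8 ratio at MAF<{fc['maf_cut']:g}: "
                     f"{fc['ratio']:.2f} ({fc['n_lax']}/{fc['n_strict']})")
    for name, ts in s["two_step"].items():
        lines.append(f"- {name}: two-step step-2 removed {ts['n_removed_step2']} "
                     f"({100 * ts['frac_step1_survivors_low_info']:.2f}% of step-1 survivors)")
    return "\n".join(lines) + "\n", s
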