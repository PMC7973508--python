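"""Synthetic haplotype data with known truth.

Generates a phased reference panel, a diploid study cohort copied from
it, an array-like typed-site subset, corrupted genotype calls, and an
external minor-allele-frequency lookup table playing the role of a
public variant database.  The generator statistically emulates a 2 Mb
fine-mapping region: ~13.5 biallelic SNPs per Kb, a cohort of ~1,000
individuals typed at ~6.5% of sites, genotyping error and missingness
sufficient that a standard GWAS quality control removes a nontrivial
fraction of typed SNPs.

The haplotype model is mosaic copying: founder haplotypes drawn from a
1/f allele-frequency spectrum, and every further haplotype a
recombination mosaic of the founders (switch points Poisson in physical
distance) with per-site mutation flips.  This creates decaying linkage
disequilibrium -- what the imputer needs -- without the machinery of a
full coalescent simulation.

One root seed drives everything through named substreams, so toggling
error injection does not perturb panel generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from imputefilter.io_formats import (
    MISSING,
    GenotypeMatrix,
    HaplotypePanel,
    write_gen,
    write_hap_legend,
    write_maf_table,
    write_vcf,
    genotypes_to_gen,
)

__all__ = [
    "DEFAULT_SEED",
    "SimulationConfig",
    "TruthBundle",
    "generate_haplotype_pool",
    "generate_study_cohort",
    "select_typed_sites",
    "inject_errors",
    "build_external_maf_table",
    "simulate_truth_bundle",
    "write_truth_bundle",
]

DEFAULT_SEED = 1411139299

# fixed substream identifiers; order is part of the determinism contract
_STREAMS = ("panel", "cohort", "typing", "errors", "maf_table")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic truth bundle.

    Defaults are a desk-scale analogue of a 2 Mb fine-mapping region:
    the typed fraction (~6.5%) and site density (13.545/Kb) match the
    full-scale setting, while haplotype and site counts are reduced so a
    paired experiment completes in minutes.  ``full_scale_config``
    returns the full-size setting (2,184 reference haplotypes, 27,090
    sites, 1,031 individuals, 1,762 typed SNPs).
    """

    n_ref_haplotypes: int = 2000
    n_study: int = 1031
    region_length_bp: int = 221_560  # keeps density at ~13.545 sites/Kb
    n_sites: int = 3_000
    n_typed: int = 195  # ~6.5% of sites, the array fraction at full scale
    n_founders: int = 1500
    recomb_rate_per_bp: float = 1e-5
    mutation_rate_per_site: float = 4e-4
    genotype_error_rate: float = 0.002
    missing_rate: float = 0.015
    bad_site_fraction: float = 0.03
    n_typed_not_in_reference: int = 0
    maf_table_null_fraction: float = 0.01
    maf_table_absent_fraction: float = 0.005
    maf_table_discordant_fraction: float = 0.005
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_typed > self.n_sites:
            raise ValueError("n_typed must not exceed n_sites")
        if self.region_length_bp <= 0:
            raise ValueError("region_length_bp must be positive")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founder haplotypes")
        for name in ("recomb_rate_per_bp", "mutation_rate_per_site",
                     "genotype_error_rate", "missing_rate", "bad_site_fraction",
                     "maf_table_null_fraction", "maf_table_absent_fraction",
                     "maf_table_discordant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_sites > self.region_length_bp:
            raise ValueError("cannot place more sites than base pairs")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-purpose random stream derived from the seed."""
        if stream not in _STREAMS:
            raise KeyError(f"unknown stream {stream!r}")
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS.index(stream),))
        return np.random.default_rng(ss)

    @classmethod
    def full_scale_config(cls, **overrides) -> "SimulationConfig":
        """The full-size setting (slow: hours, not minutes)."""
        params = dict(
            n_ref_haplotypes=2184, n_study=1031, region_length_bp=2_000_000,
            n_sites=27_090, n_typed=1762, n_founders=60,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class TruthBundle:
    """Everything one paired experiment needs, with truth retained.

    Study truth haplotypes are defined at all sites; observed genotypes
    only at typed sites.  ``bad_site_positions`` and the maf-table
    injection bookkeeping exist so tests can check the corruption did
    what it claims.
    """

    config: SimulationConfig
    reference_panel: HaplotypePanel
    study_truth_haplotypes: HaplotypePanel
    typed_site_index: np.ndarray  # indices into the truth site axis
    observed_genotypes: GenotypeMatrix
    external_maf_table: dict[str, tuple[str, float]]
    bad_site_positions: np.ndarray = field(default_factory=lambda: np.array([], int))
    maf_table_injections: Mapping[str, list[str]] = field(default_factory=dict)

    @property
    def typed_positions(self) -> np.ndarray:
        return self.study_truth_haplotypes.positions[self.typed_site_index]


def _mosaic_copy(sources: np.ndarray, positions: np.ndarray, n_out: int,
                 recomb_rate: float, mutation_rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Build n_out haplotypes as recombination mosaics of ``sources``."""
    n_src, n_sites = sources.shape
    gaps = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-recomb_rate * gaps)
    out = np.empty((n_out, n_sites), dtype=np.uint8)
    for h in range(n_out):
        switch = rng.random(n_sites - 1) < p_switch
        n_seg = 1 + int(switch.sum())
        seg_src = rng.integers(0, n_src, size=n_seg)
        src_per_site = seg_src[np.concatenate(([0], np.cumsum(switch)))]
        hap = sources[src_per_site, np.arange(n_sites)]
        if mutation_rate > 0:
            flips = rng.random(n_sites) < mutation_rate
            hap = np.where(flips, 1 - hap, hap)
        out[h] = hap
    return out


def generate_haplotype_pool(cfg: SimulationConfig) -> HaplotypePanel:
    """Generate the phased reference panel.

    Founders draw each site's allele-1 probability from a spectrum
    proportional to 1/f, truncated to [1/(2*n_ref_haplotypes), 0.5];
    the remaining haplotypes are founder mosaics.  Positions are uniform
    without replacement over the region and sorted.
    """
    rng = cfg.rng("panel")
    positions = np.sort(rng.choice(cfg.region_length_bp, size=cfg.n_sites,
                                   replace=False)) + 1  # 1-based
    f_min = 1.0 / (2.0 * cfg.n_ref_haplotypes)
    u = rng.random(cfg.n_sites)
    freqs = f_min * (0.5 / f_min) ** u  # inverse CDF of density ∝ 1/f
    founders = (rng.random((cfg.n_founders, cfg.n_sites)) < freqs).astype(np.uint8)
    n_rest = cfg.n_ref_haplotypes - cfg.n_founders
    if n_rest < 0:
        founders = founders[: cfg.n_ref_haplotypes]
        haps = founders
    else:
        rest = _mosaic_copy(founders, positions, n_rest, cfg.recomb_rate_per_bp,
                            cfg.mutation_rate_per_site, rng)
        haps = np.vstack([founders, rest])
    ids = np.array([f"snp{p}" for p in positions])
    return HaplotypePanel(
        positions=positions, haplotypes=haps, ids=ids,
        allele_a=np.full(cfg.n_sites, "A"), allele_b=np.full(cfg.n_sites, "G"),
    )


def generate_study_cohort(panel: HaplotypePanel, cfg: SimulationConfig) -> HaplotypePanel:
    """Build 2*n_study truth haplotypes by mosaic copying from the panel."""
    if panel.n_haplotypes == 0:
        raise ValueError("reference panel is empty")
    rng = cfg.rng("cohort")
    haps = _mosaic_copy(panel.haplotypes, panel.positions, 2 * cfg.n_study,
                        cfg.recomb_rate_per_bp, cfg.mutation_rate_per_site, rng)
    return HaplotypePanel(
        positions=panel.positions.copy(), haplotypes=haps, ids=panel.ids.copy(),
        allele_a=panel.allele_a.copy(), allele_b=panel.allele_b.copy(),
        chrom=panel.chrom,
    )


def select_typed_sites(panel: HaplotypePanel, cfg: SimulationConfig) -> np.ndarray:
    """Choose the array content: n_typed site indices, sorted.

    Sampling weight grows with reference MAF (genotyping arrays favour
    common variants) but keeps rare sites in play, so a MAF-based QC
    still has something to remove.
    """
    rng = cfg.rng("typing")
    if cfg.n_typed == panel.n_sites:
        return np.arange(panel.n_sites)
    weights = np.sqrt(panel.maf()) + 0.03
    weights /= weights.sum()
    idx = rng.choice(panel.n_sites, size=cfg.n_typed, replace=False, p=weights)
    return np.sort(idx)


def inject_errors(truth: HaplotypePanel, typed_index: np.ndarray,
                  cfg: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Corrupt truth genotypes at typed sites into observed array calls.

    Ordinary sites perturb a call by one genotype category (clipped)
    with ``genotype_error_rate``; a ``bad_site_fraction`` of sites gets
    a 10x error rate whose errors are forced to heterozygote, creating
    the heterozygote excess a Hardy-Weinberg filter catches.  Each call
    is independently missing with ``missing_rate``.

    Returns the observed genotype matrix and the bad-site positions.
    """
    rng = cfg.rng("errors")
    n_typed = typed_index.size
    h = truth.haplotypes[:, typed_index]
    g = (h[0::2] + h[1::2]).T.astype(np.int8)  # (n_typed, n_study)
    n_study = g.shape[1]

    n_bad = int(round(cfg.bad_site_fraction * n_typed))
    bad_local = rng.choice(n_typed, size=n_bad, replace=False) if n_bad else np.array([], int)
    is_bad = np.zeros(n_typed, dtype=bool)
    is_bad[bad_local] = True

    rate = np.where(is_bad, min(1.0, 10.0 * cfg.genotype_error_rate),
                    cfg.genotype_error_rate)
    err = rng.random(g.shape) < rate[:, None]
    # ordinary errors: +/-1 category, clipped to {0,1,2}
    step = rng.choice(np.array([-1, 1], dtype=np.int8), size=g.shape)
    perturbed = np.clip(g + step, 0, 2).astype(np.int8)
    # bad-site errors: forced heterozygote
    perturbed = np.where(is_bad[:, None], np.int8(1), perturbed)
    g = np.where(err, perturbed, g)

    miss = rng.random(g.shape) < cfg.missing_rate
    g = np.where(miss, np.int8(MISSING), g)

    samples = [f"ind{i:04d}" for i in range(n_study)]
    gm = GenotypeMatrix(
        positions=truth.positions[typed_index], ids=truth.ids[typed_index],
        allele_a=truth.allele_a[typed_index], allele_b=truth.allele_b[typed_index],
        genotypes=g, samples=samples, chrom=truth.chrom,
    )
    return gm, truth.positions[typed_index][bad_local]


def build_external_maf_table(panel: HaplotypePanel, cfg: SimulationConfig
                             ) -> tuple[dict[str, tuple[str, float]], dict[str, list[str]]]:
    """Database-like MAF table from panel frequencies, with injected flaws.

    A configurable fraction of records is nulled (maf set to 0), dropped
    entirely, or given a discordant minor-allele label, exercising the
    database cross-check.  Returns the table and the injection
    bookkeeping (lists of affected ids per flaw).
    """
    rng = cfg.rng("maf_table")
    f = panel.allele_freq()
    maf = np.minimum(f, 1.0 - f)
    minor = np.where(f <= 0.5, panel.allele_b, panel.allele_a)
    n = panel.n_sites
    flaws = {"null": [], "absent": [], "discordant": []}
    roll = rng.random(n)
    t_null = cfg.maf_table_null_fraction
    t_abs = t_null + cfg.maf_table_absent_fraction
    t_disc = t_abs + cfg.maf_table_discordant_fraction
    table: dict[str, tuple[str, float]] = {}
    for i in range(n):
        vid = str(panel.ids[i])
        if roll[i] < t_null:
            flaws["null"].append(vid)
            table[vid] = (str(minor[i]), 0.0)
        elif roll[i] < t_abs:
            flaws["absent"].append(vid)
        elif roll[i] < t_disc and maf[i] > 0:
            flaws["discordant"].append(vid)
            other = panel.allele_a[i] if minor[i] == panel.allele_b[i] else panel.allele_b[i]
            table[vid] = (str(other), float(maf[i]))
        else:
            table[vid] = (str(minor[i]), float(maf[i]))
    return table, flaws


def simulate_truth_bundle(cfg: SimulationConfig) -> TruthBundle:
    """Run the whole generator: panel, cohort, typing, corruption, table."""
    panel = generate_haplotype_pool(cfg)
    cohort = generate_study_cohort(panel, cfg)
    typed_index = select_typed_sites(panel, cfg)
    observed, bad_pos = inject_errors(cohort, typed_index, cfg)

    if cfg.n_typed_not_in_reference > 0:
        # emulate typed variants absent from the reference panel
        rng = cfg.rng("typing")  # fresh stream copy; consumed draws replayed
        w = np.sqrt(panel.maf()) + 0.03
        rng.choice(panel.n_sites, size=cfg.n_typed, replace=False, p=w / w.sum())
        held = rng.choice(typed_index, size=cfg.n_typed_not_in_reference, replace=False)
        keep = np.setdiff1d(np.arange(panel.n_sites), held)
        panel = panel.subset_sites(keep)

    table, flaws = build_external_maf_table(panel, cfg)
    return TruthBundle(
        config=cfg, reference_panel=panel, study_truth_haplotypes=cohort,
        typed_site_index=typed_index, observed_genotypes=observed,
        external_maf_table=table, bad_site_positions=bad_pos,
        maf_table_injections=flaws,
    )


def write_truth_bundle(bundle: TruthBundle, out_dir: str | Path) -> dict[str, str]:
    """Serialize a bundle: VCF + hap/legend reference, GEN/SAMPLE study
    genotypes, TSV MAF table, YAML manifest.  Returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "reference_vcf": "reference.vcf",
        "reference_hap": "reference.hap",
        "reference_legend": "reference.legend",
        "study_gen": "study.gen",
        "study_sample": "study.sample",
        "maf_table": "external_maf.tsv",
        "manifest": "manifest.yaml",
    }
    write_vcf(bundle.reference_panel, out / files["reference_vcf"])
    write_hap_legend(bundle.reference_panel, out / files["reference_hap"],
                     out / files["reference_legend"])
    gp = genotypes_to_gen(bundle.observed_genotypes)
    write_gen(gp, out / files["study_gen"], out / files["study_sample"])
    panel = bundle.reference_panel
    pos_of = {str(panel.ids[i]): int(panel.positions[i]) for i in range(panel.n_sites)}
    write_maf_table(
        ((vid, panel.chrom, pos_of.get(vid, 0), allele, maf)
         for vid, (allele, maf) in bundle.external_maf_table.items()),
        out / files["maf_table"])
    manifest = {
        "config": asdict(bundle.config),
        "files": files,
        "n_reference_sites": int(panel.n_sites),
        "n_typed": int(bundle.typed_site_index.size),
        "n_bad_sites": int(bundle.bad_site_positions.size),
    }
    with open(out / files["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return files
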