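"""GWAS-style pre-imputation quality control of typed genotypes.

Filters: sample missingness, then per-variant MAF, call-rate and a
two-sided Hardy-Weinberg exact test.  Every threshold is configurable
and every filter can be disabled, which makes ``apply_qc`` the identity
on the data payload -- the "no QC" arm of a paired experiment.

The Hardy-Weinberg exact p-value is the classic two-sided conditional
test: the sum of probabilities of all heterozygote counts (same sample
total, same minor-allele count) no more likely than the observed one,
computed by the numerically stable ratio recurrence.  No mid-p
adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from imputefilter.io_formats import MISSING, GenotypeMatrix

__all__ = [
    "QCConfig",
    "QCReport",
    "maf_from_genotypes",
    "hwe_exact_test",
    "apply_qc",
]


@dataclass
class QCConfig:
    """Thresholds of the variant/sample QC.

    Defaults follow common GWAS practice: drop variants with minor
    allele frequency below 1%, call-rate below 95%, or Hardy-Weinberg
    exact p below 1e-6; drop samples missing more than 5% of calls.
    """

    maf_min: float = 0.01
    variant_missing_max: float = 0.05
    hwe_p_min: float = 1e-6
    sample_missing_max: float = 0.05
    enabled: dict = field(default_factory=lambda: {
        "maf": True, "variant_missing": True, "hwe": True, "sample_missing": True,
    })

    def __post_init__(self) -> None:
        for name in ("maf_min", "variant_missing_max", "hwe_p_min",
                     "sample_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def disabled(cls) -> "QCConfig":
        """The no-QC arm: every filter off."""
        return cls(enabled={k: False for k in
                            ("maf", "variant_missing", "hwe", "sample_missing")})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QCConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class QCReport:
    """Per-variant and per-sample verdicts plus summary counts."""

    variants: pd.DataFrame   # id, pos, n_called, maf, missing_rate, hwe_p, verdict, failed_filters
    samples: pd.DataFrame    # sample, missing_rate, verdict
    summary: dict

    @property
    def fraction_removed(self) -> float:
        return self.summary["variants_removed"] / max(1, self.summary["variants_total"])


def maf_from_genotypes(n0: int, n1: int, n2: int) -> float:
    """Minor-allele frequency from called genotype counts.

    f_B = (n1 + 2*n2) / (2*(n0+n1+n2)); the minor allele is whichever
    is rarer, so the result lies in [0, 0.5].  Raises on zero calls.
    """
    total = n0 + n1 + n2
    if total < 1:
        raise ValueError("MAF undefined with zero called genotypes")
    f_b = (n1 + 2 * n2) / (2.0 * total)
    return min(f_b, 1.0 - f_b)


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided Hardy-Weinberg exact p-value.

    Conditions on the sample size and the minor-allele count; sums the
    conditional probabilities of every heterozygote count whose
    probability does not exceed the observed configuration's.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotype")
    n_minor = n_het + 2 * min(n_hom_major, n_hom_minor)
    # the conditional distribution depends only on (n, rare-allele count)
    n_rare = min(n_minor, 2 * n - n_minor)
    obs_het = n_het
    if n_rare == 0:
        return 1.0

    # heterozygote counts share the parity of the rare-allele count
    het_min = n_rare % 2
    het_max = n_rare
    # unnormalized probabilities via the stable ratio recurrence, anchored
    # mid-range to avoid overflow
    hets = list(range(het_min, het_max + 1, 2))
    probs = np.empty(len(hets))
    mid_idx = len(hets) // 2
    probs[mid_idx] = 1.0
    for i in range(mid_idx + 1, len(hets)):
        h = hets[i]  # from h-2 to h
        rare_hom = (n_rare - (h - 2)) // 2
        common_hom = n - (h - 2) - rare_hom
        probs[i] = probs[i - 1] * (4.0 * rare_hom * common_hom) / (h * (h - 1.0))
    for i in range(mid_idx - 1, -1, -1):
        h = hets[i]  # from h+2 down to h
        rare_hom = (n_rare - (h + 2)) // 2
        common_hom = n - (h + 2) - rare_hom
        probs[i] = probs[i + 1] * ((h + 2.0) * (h + 1.0)) / (4.0 * (rare_hom + 1.0) * (common_hom + 1.0))
    probs /= probs.sum()
    p_obs = probs[hets.index(obs_het)]
    # tolerate float fuzz when comparing configuration probabilities
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _variant_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    g = gm.genotypes
    called = g != MISSING
    n_called = called.sum(axis=1)
    n0 = ((g == 0) & called).sum(axis=1)
    n1 = (g == 1).sum(axis=1)
    n2 = (g == 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_b = (n1 + 2 * n2) / (2.0 * np.maximum(n_called, 1))
    maf = np.where(n_called > 0, np.minimum(f_b, 1.0 - f_b), np.nan)
    missing_rate = 1.0 - n_called / g.shape[1]
    hwe_p = np.array([
        hwe_exact_test(int(a), int(b), int(c)) if k > 0 else np.nan
        for a, b, c, k in zip(n0, n1, n2, n_called)
    ])
    return pd.DataFrame({
        "id": gm.ids, "pos": gm.positions, "n_called": n_called,
        "maf": maf, "missing_rate": missing_rate, "hwe_p": hwe_p,
    })


def apply_qc(gm: GenotypeMatrix, cfg: QCConfig) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample QC, then variant QC on the remaining samples.

    Returns the filtered matrix and a report listing every failure with
    its reasons.  The input matrix is never modified.  Each variant's
    verdict depends only on its own genotypes, never on other variants.
    """
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    en = cfg.enabled

    sample_missing = (gm.genotypes == MISSING).mean(axis=0)
    sample_fail = np.zeros(gm.n_samples, dtype=bool)
    if en.get("sample_missing", True):
        sample_fail = sample_missing > cfg.sample_missing_max
    samples_df = pd.DataFrame({
        "sample": gm.samples, "missing_rate": sample_missing,
        "verdict": np.where(sample_fail, "fail", "pass"),
    })
    keep_samples = np.flatnonzero(~sample_fail)
    gm_s = gm.subset(sample_index=keep_samples) if sample_fail.any() else gm

    stats = _variant_stats(gm_s)
    reasons: list[list[str]] = [[] for _ in range(gm_s.n_variants)]
    undefined = stats["n_called"].to_numpy() == 0
    for i in np.flatnonzero(undefined):
        reasons[i].append("variant_missing")  # no calls at all
    if en.get("maf", True):
        bad = (stats["maf"].to_numpy() < cfg.maf_min) & ~undefined
        for i in np.flatnonzero(bad):
            reasons[i].append("maf")
    if en.get("variant_missing", True):
        bad = (stats["missing_rate"].to_numpy() > cfg.variant_missing_max) & ~undefined
        for i in np.flatnonzero(bad):
            reasons[i].append("variant_missing")
    if en.get("hwe", True):
        bad = (stats["hwe_p"].to_numpy() < cfg.hwe_p_min) & ~undefined
        for i in np.flatnonzero(bad):
            reasons[i].append("hwe")

    fail = np.array([len(r) > 0 for r in reasons])
    variants_df = stats.copy()
    variants_df["verdict"] = np.where(fail, "fail", "pass")
    variants_df["failed_filters"] = [",".join(r) for r in reasons]

    keep_variants = np.flatnonzero(~fail)
    out = gm_s.subset(variant_index=keep_variants)
    summary = {
        "variants_total": int(gm.n_variants),
        "variants_removed": int(fail.sum()),
        "variants_kept": int(keep_variants.size),
        "fraction_removed": float(fail.sum() / gm.n_variants),
        "samples_total": int(gm.n_samples),
        "samples_removed": int(sample_fail.sum()),
        "removal_reasons": {
            r: int(sum(r in rs for rs in reasons))
            for r in ("maf", "variant_missing", "hwe")
        },
    }
    return out, QCReport(variants=variants_df, samples=samples_df, summary=summary)
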