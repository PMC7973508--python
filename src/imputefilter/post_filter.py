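"""Post-imputation filtration strategies.

Three kinds: no filtration, a single information-score threshold
(typically 0.3 or 0.8), and a two-step procedure -- first remove
imputed variants whose minor-allele frequency falls below the cohort's
heterozygote-equivalent frequency (about 1.5 heterozygous individuals'
worth, recomputed per dataset), then remove survivors with an
information score below 0.3.  Two-step survivors with info in
[0.3, 0.8) are flagged rather than discarded, preserving rare variants
a blanket 0.8 cutoff would destroy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterStrategy",
    "SurvivalRow",
    "het_equivalent_threshold",
    "apply_strategy",
    "survival_by_bin",
    "fold_change_report",
]

FLAG_BAND = (0.3, 0.8)


@dataclass
class FilterStrategy:
    """One filtration recipe.

    kind ``none`` passes everything; ``info_threshold`` keeps variants
    with info strictly above ``info_min``; ``two_step`` keeps typed
    variants (if exempt) or those with maf >= ``maf_min``, then keeps
    survivors with info >= ``info_min``.
    """

    kind: str = "two_step"  # none | info_threshold | two_step
    info_min: float = 0.3
    maf_min: float = 0.0
    exempt_typed: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("none", "info_threshold", "two_step"):
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if not 0.0 <= self.info_min <= 1.0:
            raise ValueError("info_min must lie in [0, 1]")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")


@dataclass
class SurvivalRow:
    """Accounting for one strategy application."""

    strategy: str
    n_input: int
    n_surviving: int
    n_removed_step1: int
    n_removed_step2: int
    frac_step1_survivors_low_info: float  # share of step-1 survivors with info < info_min


def het_equivalent_threshold(n_samples: int, het_equivalents: float = 1.5) -> float:
    """MAF contributed by ``het_equivalents`` heterozygous individuals
    among ``n_samples`` diploids: c / (2N).

    With c = 1.5 and about a thousand samples this lands just above the
    one-heterozygote minimum observable frequency, the recommended
    step-1 anchor; c = 0 disables the filter.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if het_equivalents < 0:
        raise ValueError("het_equivalents must be non-negative")
    return het_equivalents / (2.0 * n_samples)


def apply_strategy(run: pd.DataFrame, strategy: FilterStrategy
                   ) -> tuple[pd.DataFrame, SurvivalRow]:
    """Apply a strategy to a variant-quality table (needs columns
    ``maf``, ``info``, ``source``; as from
    ``metrics.variant_quality_table``).

    Returns the surviving rows (two-step survivors gain a
    ``flag_low_info`` boolean for the [0.3, 0.8) band) and the survival
    accounting, including the share of step-1 survivors that step 2
    then removes -- the diagnostic for whether the MAF step already did
    the quality work.
    """
    n_in = len(run)
    if strategy.kind == "none":
        return run.copy(), SurvivalRow("none", n_in, n_in, 0, 0, 0.0)
    if strategy.kind == "info_threshold":
        keep = run["info"] > strategy.info_min
        out = run[keep].copy()
        name = f"info>{strategy.info_min:g}"
        return out, SurvivalRow(name, n_in, len(out), 0, int((~keep).sum()), 0.0)

    # two_step
    step1 = run["maf"] >= strategy.maf_min
    if strategy.exempt_typed:
        step1 |= run["source"] == "typed"
    s1 = run[step1]
    low_info = s1["info"] < strategy.info_min
    frac_low = float(low_info.mean()) if len(s1) else 0.0
    out = s1[~low_info].copy()
    out["flag_low_info"] = (out["info"] >= FLAG_BAND[0]) & (out["info"] < FLAG_BAND[1])
    name = f"two_step(maf>={strategy.maf_min:.3g},info>={strategy.info_min:g})"
    return out, SurvivalRow(name, n_in, len(out),
                            int((~step1).sum()), int(low_info.sum()), frac_low)


def survival_by_bin(run: pd.DataFrame,
                    strategies: list[FilterStrategy]) -> pd.DataFrame:
    """Per-bin survivor counts for each strategy, wide format.

    Raising an info threshold can only shrink every cell, so columns
    for stricter thresholds are elementwise bounded by laxer ones.
    """
    from imputefilter.metrics import MAF_BIN_LABELS

    cols = {}
    for s in strategies:
        surv, row = apply_strategy(run, s)
        counts = surv["bin"].value_counts().reindex(MAF_BIN_LABELS, fill_value=0)
        cols[row.strategy] = counts.astype(int)
    df = pd.DataFrame(cols)
    df.loc["all"] = df.sum()
    return df


def fold_change_report(run: pd.DataFrame, thresholds: tuple[float, float] = (0.3, 0.8),
                       maf_cut: float = 1e-3) -> dict:
    """Survivor-count ratios between a lax and a strict info threshold.

    The headline ratio counts variants with maf < ``maf_cut`` that
    survive info > ``thresholds[0]`` versus info > ``thresholds[1]``;
    per-bin ratios are also reported.  Zero denominators yield NaN with
    an ``undefined`` flag.
    """
    lo, hi = thresholds
    lax = run[run["info"] > lo]
    strict = run[run["info"] > hi]
    n_lax = int((lax["maf"] < maf_cut).sum())
    n_strict = int((strict["maf"] < maf_cut).sum())
    headline = n_lax / n_strict if n_strict else np.nan

    from imputefilter.metrics import MAF_BIN_LABELS

    per_bin = {}
    for label in MAF_BIN_LABELS:
        a = int((lax["bin"] == label).sum())
        b = int((strict["bin"] == label).sum())
        per_bin[label] = {"n_lax": a, "n_strict": b,
                          "ratio": a / b if b else np.nan}
    return {
        "thresholds": (lo, hi), "maf_cut": maf_cut,
        "n_lax": n_lax, "n_strict": n_strict,
        "ratio": headline, "undefined": n_strict == 0,
        "per_bin": per_bin,
        "total_ratio": len(lax) / len(strict) if len(strict) else np.nan,
    }
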