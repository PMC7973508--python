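"""Paired comparison of two imputation runs (QC arm vs no-QC arm).

Builds the variant-keyed paired table, runs per-MAF-class paired
Wilcoxon signed-rank tests with Hodges-Lehmann pseudomedians, counts
bin migrations between arms, cross-checks imputed frequencies against
an external database-style MAF table, and flags positions carrying two
distinct imputed records (dual imputations).

Zero differences are dropped before ranking (the classical Wilcoxon
convention, matching R's ``wilcox.test`` default); the exact null is
used for up to 25 nonzero tie-free pairs and the tie-corrected,
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from imputefilter.io_formats import VariantRecord
from imputefilter.metrics import MAF_BIN_LABELS

__all__ = [
    "EXACT_N_MAX",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "hodges_lehmann_pseudomedian",
    "spearman_corr",
    "build_paired_table",
    "per_bin_tests",
    "bin_migration_matrix",
    "bin_count_summary",
    "dbsnp_crosscheck",
    "detect_dual_imputation",
    "significance_stars",
    "STAR_SCHEME_TWO_SIDED",
    "STAR_SCHEME_ONE_SIDED",
]

EXACT_N_MAX = 25

# two-sided levels, and the halved one-sided levels used for one-tailed tables
STAR_SCHEME_TWO_SIDED = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))
STAR_SCHEME_ONE_SIDED = ((5e-5, "****"), (5e-4, "***"), (5e-3, "**"), (2.5e-2, "*"))


def significance_stars(p: float, scheme=STAR_SCHEME_TWO_SIDED) -> str:
    for level, stars in scheme:
        if p < level:
            return stars
    return ""


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_nonzero: int
    n_zero: int
    method: str  # "exact" | "approx" | "degenerate"


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray,
                         alternative: str = "two-sided") -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on x - y.

    Zeros are dropped; with no nonzero differences the result is the
    degenerate p = 1.  Exact enumeration when the nonzero count is at
    most 25 and |differences| are tie-free; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    d = x - y
    nz = d[d != 0]
    n_zero = d.size - nz.size
    if nz.size == 0:
        return WilcoxonResult(0.0, 1.0, 0, n_zero, "degenerate")
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= EXACT_N_MAX and not has_ties) else "approx"
    res = sps.wilcoxon(nz, alternative=alternative, zero_method="wilcox",
                       correction=(method == "approx"), method=method)
    return WilcoxonResult(float(res.statistic if alternative != "two-sided"
                                else _w_plus(nz)),
                          float(res.pvalue), int(nz.size), int(n_zero), method)


def _w_plus(d: np.ndarray) -> float:
    ranks = sps.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def hodges_lehmann_pseudomedian(d: np.ndarray) -> float:
    """Median of all n(n+1)/2 Walsh averages (d_i + d_j)/2, i <= j."""
    d = np.asarray(d, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one difference")
    iu = np.triu_indices(d.size)
    walsh = (d[iu[0]] + d[iu[1]]) / 2.0
    return float(np.median(walsh))


def spearman_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    ra, rb = sps.rankdata(a), sps.rankdata(b)
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    return float(np.corrcoef(ra, rb)[0, 1])


@dataclass
class PairedRunTable:
    """Inner join of two per-variant quality tables on the variant key."""

    table: pd.DataFrame          # key, id, pos, maf/info/bin/minor per arm
    only_in_noqc: pd.DataFrame
    only_in_qc: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @property
    def n_allele_discordant(self) -> int:
        return int(self.table["allele_discordant"].sum())


def build_paired_table(run_noqc: pd.DataFrame, run_qc: pd.DataFrame) -> PairedRunTable:
    """Join two variant-quality tables (columns as produced by
    ``metrics.variant_quality_table``) on the identity key.

    Variants present in only one run are reported separately, never
    silently dropped.  The allele-discordance flag marks pairs whose
    polymorphic minor-allele labels disagree between arms.
    """
    for name, run in (("no-QC", run_noqc), ("QC", run_qc)):
        dup = run["key"][run["key"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate variant keys in {name} run: {list(dup)[:5]}")
    merged = run_noqc.merge(run_qc, on="key", how="outer", suffixes=("_noqc", "_qc"),
                            indicator=True)
    both = merged[merged["_merge"] == "both"].drop(columns="_merge").copy()
    left = merged[merged["_merge"] == "left_only"]
    right = merged[merged["_merge"] == "right_only"]
    both["allele_discordant"] = (
        (both["minor_allele_noqc"] != both["minor_allele_qc"])
        & (both["maf_noqc"] > 0) & (both["maf_qc"] > 0)
    )
    keep_left = [c for c in merged.columns if c.endswith("_noqc") or c == "key"]
    keep_right = [c for c in merged.columns if c.endswith("_qc") or c == "key"]
    return PairedRunTable(
        table=both.reset_index(drop=True),
        only_in_noqc=left[keep_left].reset_index(drop=True),
        only_in_qc=right[keep_right].reset_index(drop=True),
    )


def per_bin_tests(paired: PairedRunTable, quantity: str = "maf",
                  binning_arm: str = "noqc",
                  alternative: str = "two-sided") -> pd.DataFrame:
    """Per-MAF-class paired tests of a quantity between arms.

    One row per bin of the designated arm's classification plus a
    pooled all-variants row.  Each row carries counts, means, sds, the
    two-sided and one-sided-greater (no-QC > QC) p-values, the
    Hodges-Lehmann pseudomedian of the differences, and significance
    stars.  Bins with fewer than two pairs report descriptives only.
    """
    if quantity not in ("maf", "info"):
        raise ValueError("quantity must be 'maf' or 'info'")
    t = paired.table
    bin_col = f"bin_{binning_arm}"
    xcol, ycol = f"{quantity}_noqc", f"{quantity}_qc"
    groups = [(label, t[t[bin_col] == label]) for label in MAF_BIN_LABELS]
    groups.append(("all", t))
    rows = []
    for label, g in groups:
        x, y = g[xcol].to_numpy(), g[ycol].to_numpy()
        row = {
            "bin": label, "n": len(g),
            "mean_noqc": x.mean() if len(g) else np.nan,
            "sd_noqc": x.std(ddof=1) if len(g) > 1 else np.nan,
            "mean_qc": y.mean() if len(g) else np.nan,
            "sd_qc": y.std(ddof=1) if len(g) > 1 else np.nan,
        }
        if len(g) >= 2:
            two = wilcoxon_signed_rank(x, y, "two-sided")
            one = wilcoxon_signed_rank(x, y, "greater")
            row.update({
                "p_two_sided": two.p_value,
                "p_one_sided_greater": one.p_value,
                "n_nonzero": two.n_nonzero, "n_zero": two.n_zero,
                "pseudomedian": hodges_lehmann_pseudomedian(x - y) if len(g) else np.nan,
                "stars_two_sided": significance_stars(two.p_value),
                "stars_one_sided": significance_stars(one.p_value,
                                                      STAR_SCHEME_ONE_SIDED),
            })
        else:
            row.update({"p_two_sided": np.nan, "p_one_sided_greater": np.nan,
                        "n_nonzero": 0, "n_zero": len(g),
                        "pseudomedian": np.nan,
                        "stars_two_sided": "", "stars_one_sided": ""})
        rows.append(row)
    return pd.DataFrame(rows)


def bin_migration_matrix(paired: PairedRunTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts of variants by (bin without QC, bin with QC).

    Returns (counts, row percentages); percentages are row-normalized
    and rounded to one decimal.  Diagonal cells are class-stable
    variants; off-diagonal cells are migrations.
    """
    t = paired.table
    counts = pd.crosstab(t["bin_noqc"], t["bin_qc"])
    counts = counts.reindex(index=MAF_BIN_LABELS, columns=MAF_BIN_LABELS,
                            fill_value=0)
    counts.index.name, counts.columns.name = "bin_noqc", "bin_qc"
    row_sums = counts.sum(axis=1).replace(0, np.nan)
    pct = (100.0 * counts.div(row_sums, axis=0)).round(1).fillna(0.0)
    return counts, pct


def bin_count_summary(counts: dict[str, int] | pd.Series) -> dict:
    """Arithmetic summary of one arm's per-bin variant counts.

    Reports the total, the share of variants with MAF below 0.01 with
    and without the null class, and each aggregate class's percentage
    of the total (the stated denominator is always this arm's total).
    """
    s = pd.Series(counts).reindex(MAF_BIN_LABELS, fill_value=0)
    total = int(s.sum())
    below_001 = int(s[["null", "very_rare_I", "very_rare_II", "rare_I", "rare_II"]].sum())
    agg = {
        "null": int(s["null"]),
        "very_rare": int(s["very_rare_I"] + s["very_rare_II"]),
        "rare": int(s["rare_I"] + s["rare_II"]),
        "low": int(s["low"]), "common": int(s["common"]), "high": int(s["high"]),
    }
    return {
        "total": total,
        "pct_below_001_incl_null": 100.0 * below_001 / total if total else np.nan,
        "pct_below_001_excl_null": 100.0 * (below_001 - s["null"]) / total if total else np.nan,
        "pct_by_class": {k: 100.0 * v / total if total else np.nan
                         for k, v in agg.items()},
    }


def dbsnp_crosscheck(run: pd.DataFrame, table: dict[str, tuple[str, float]]
                     ) -> tuple[pd.DataFrame, dict]:
    """Cross-check a run's imputed MAFs against an external MAF table.

    Per-variant status: ``absent`` (no database record), ``null_both``
    (zero frequency on both sides), ``null_in_db`` (database zero,
    imputed nonzero), ``allele_discordant`` (minor-allele labels
    disagree while both polymorphic), else ``concordant``.  The summary
    carries status counts and the Spearman correlation of MAFs over
    concordant records.
    """
    statuses = []
    for _, row in run.iterrows():
        rec = table.get(row["id"])
        if rec is None:
            statuses.append("absent")
            continue
        db_allele, db_maf = rec
        if db_maf == 0.0 and row["maf"] == 0.0:
            statuses.append("null_both")
        elif db_maf == 0.0:
            statuses.append("null_in_db")
        elif row["maf"] > 0 and db_allele != row["minor_allele"]:
            statuses.append("allele_discordant")
        else:
            statuses.append("concordant")
    out = run[["key", "id", "maf", "minor_allele"]].copy()
    out["status"] = statuses
    out["db_maf"] = [table.get(i, (None, np.nan))[1] for i in run["id"]]
    conc = out[out["status"] == "concordant"]
    rho = (spearman_corr(conc["maf"].to_numpy(), conc["db_maf"].to_numpy())
           if len(conc) >= 2 and conc["maf"].nunique() > 1
           and conc["db_maf"].nunique() > 1 else np.nan)
    summary = {"counts": dict(Counter(statuses)), "spearman_concordant": rho}
    return out, summary


def detect_dual_imputation(variants: list[VariantRecord]) -> list[tuple[VariantRecord, VariantRecord]]:
    """All unordered pairs of records sharing (chrom, pos) but differing
    in variant class or alleles -- e.g. a SNP and a structural variant
    imputed at the same locus."""
    by_pos: dict[tuple[str, int], list[VariantRecord]] = {}
    for v in variants:
        by_pos.setdefault((v.chrom, v.pos), []).append(v)
    pairs = []
    for recs in by_pos.values():
        if len(recs) < 2:
            continue
        for a, b in combinations(recs, 2):
            if (a.variant_class != b.variant_class
                    or {a.allele_a, a.allele_b} != {b.allele_a, b.allele_b}):
                pairs.append((a, b))
    return pairs
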