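"""Per-variant imputation quality metrics and MAF stratification.

Quantities: allele dosage, imputed minor-allele frequency, the
IMPUTE2/SNPTEST information score, minor-allele-frequency class labels,
masked-genotype concordance and squared dosage correlation (r2_type0),
and 2 Mb windowed summaries of a variant set.

The MAF class scheme partitions (0, 0.5] into null, very rare (two
subclasses), rare (two subclasses), low, common and high bins with
edges {0, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 5e-2, 1e-1, 5e-1}; each bin is
left-open, right-closed, and a MAF of exactly 0 belongs to the null bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from imputefilter.io_formats import MISSING, GenotypeProbabilities

__all__ = [
    "MAF_BIN_EDGES",
    "MAF_BIN_LABELS",
    "MafBin",
    "dosage",
    "imputed_maf",
    "info_score",
    "classify_maf_bin",
    "concordance_masked",
    "r2_type0_masked",
    "variant_quality_table",
    "windowed_summary",
    "tukey_fence",
]

MAF_BIN_EDGES = np.array([0.0, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 5e-2, 1e-1, 5e-1])
MAF_BIN_LABELS = ("null", "very_rare_I", "very_rare_II", "rare_I", "rare_II",
                  "low", "common", "high")


@dataclass(frozen=True)
class MafBin:
    label: str
    lo: float
    hi: float

    def __contains__(self, maf: float) -> bool:
        if self.label == "null":
            return 0.0 <= maf <= self.hi
        return self.lo < maf <= self.hi


MAF_BINS = tuple(
    MafBin(MAF_BIN_LABELS[i], float(MAF_BIN_EDGES[i]), float(MAF_BIN_EDGES[i + 1]))
    for i in range(len(MAF_BIN_LABELS))
)


def dosage(probs: np.ndarray) -> np.ndarray:
    """Expected allele-B count e = p1 + 2*p2, elementwise over triplets."""
    probs = np.asarray(probs)
    return probs[..., 1] + 2.0 * probs[..., 2]


def imputed_maf(probs: np.ndarray) -> float | np.ndarray:
    """Minor-allele frequency from mean dosage.

    For one variant's (n_samples, 3) triplets returns a scalar; for a
    (n_variants, n_samples, 3) stack returns a vector.  Because dosages
    are fractional, the result can fall below the one-heterozygote
    frequency 1/(2N) that hard genotypes bound from below.
    """
    d = dosage(probs)
    f = d.mean(axis=-1) / 2.0
    return np.minimum(f, 1.0 - f)


def info_score(probs: np.ndarray) -> float | np.ndarray:
    """IMPUTE2/SNPTEST information measure of imputation certainty.

    With e_i = p1 + 2*p2, f_i = p1 + 4*p2 and theta = sum(e)/2N:

        info = 1 - sum(f_i - e_i^2) / (2N * theta * (1 - theta))

    Equals 1 when every triplet is certain (f = e^2 pointwise) and by
    convention when theta is 0 or 1; clipped to [0, 1].
    """
    probs = np.asarray(probs)
    e = probs[..., 1] + 2.0 * probs[..., 2]
    f = probs[..., 1] + 4.0 * probs[..., 2]
    n = probs.shape[-2]
    theta = e.sum(axis=-1) / (2.0 * n)
    denom = 2.0 * n * theta * (1.0 - theta)
    num = (f - e ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        info = np.where(denom > 0, 1.0 - num / np.where(denom > 0, denom, 1.0), 1.0)
    return np.clip(info, 0.0, 1.0) if np.ndim(info) else float(np.clip(info, 0.0, 1.0))


def classify_maf_bin(maf: float | np.ndarray) -> np.ndarray | str:
    """Map MAF values in [0, 0.5] to bin labels (left-open, right-closed)."""
    arr = np.asarray(maf, dtype=float)
    if np.any((arr < 0) | (arr > 0.5)):
        raise ValueError("maf must lie in [0, 0.5]")
    # snap float dust sitting within 1e-10 above an edge back into the
    # closed bin (the copying-error floor lands exactly on an edge)
    idx = np.searchsorted(MAF_BIN_EDGES[1:], arr - 1e-10, side="left")
    labels = np.array(MAF_BIN_LABELS, dtype=object)[idx]
    return str(labels) if np.ndim(maf) == 0 else labels


def concordance_masked(gp: GenotypeProbabilities, original: np.ndarray,
                       min_posterior: float = 0.0) -> float:
    """Fraction of best-guess imputed genotypes matching original calls.

    ``original`` is (n_variants, n_samples) hard genotypes at the same
    masked typed sites; missing originals are excluded.  Best guess is
    the argmax triplet, ties broken toward the lower genotype index.
    With ``min_posterior`` > 0, cells whose top probability falls below
    it are excluded (no-call) rather than counted as errors.
    """
    original = np.asarray(original)
    if original.shape != (gp.n_variants, gp.n_samples):
        raise ValueError("original genotype shape mismatch")
    best = np.argmax(gp.probs, axis=2)  # first max wins: ties -> lower index
    top = np.take_along_axis(gp.probs, best[:, :, None], axis=2)[:, :, 0]
    use = (original != MISSING) & (top >= min_posterior)
    if not use.any():
        raise ValueError("no called cells to compare")
    return float((best[use] == original[use]).mean())


def r2_type0_masked(gp: GenotypeProbabilities, original: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of imputed dosage vs original genotype.

    Returned per variant; NaN where fewer than two called samples or
    either vector has zero variance (such variants are excluded from
    r2 summaries and counted separately).
    """
    original = np.asarray(original, dtype=float)
    d = dosage(gp.probs)
    out = np.full(gp.n_variants, np.nan)
    for i in range(gp.n_variants):
        mask = original[i] != MISSING
        if mask.sum() < 2:
            continue
        x, y = d[i, mask], original[i, mask]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        out[i] = r * r
    return out


def tukey_fence(values: np.ndarray, k: float = 1.5) -> float:
    """Lower Tukey fence Q1 - k*IQR, the default outlier rule for
    flagging poorly imputed typed variants."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    q1, q3 = np.percentile(v, [25, 75])
    return float(q1 - k * (q3 - q1))


def variant_quality_table(gp: GenotypeProbabilities) -> pd.DataFrame:
    """Per-variant quality table for one imputation run.

    Columns: key, id, chrom, pos, allele_a, allele_b, variant_class,
    source, maf, minor_allele, info, bin.  The minor allele is derived
    from the dosage-based frequency; ties (freq exactly 0.5) report
    allele B.
    """
    maf = np.atleast_1d(imputed_maf(gp.probs))
    info = np.atleast_1d(info_score(gp.probs))
    freq_b = np.array([dosage(gp.probs[i]).mean() / 2.0 for i in range(gp.n_variants)])
    rows = []
    for i, v in enumerate(gp.variants):
        minor = v.allele_b if freq_b[i] <= 0.5 else v.allele_a
        rows.append({
            "key": v.key, "id": v.id, "chrom": v.chrom, "pos": v.pos,
            "allele_a": v.allele_a, "allele_b": v.allele_b,
            "variant_class": v.variant_class.value, "source": v.source,
            "maf": float(maf[i]), "minor_allele": minor, "info": float(info[i]),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["bin"] = classify_maf_bin(df["maf"].to_numpy())
    else:
        df["bin"] = pd.Series(dtype=object)
    return df


def windowed_summary(positions: np.ndarray, maf: np.ndarray,
                     window_bp: int = 2_000_000) -> pd.DataFrame:
    """Per-window variant count, density per Kb and MAF quartiles.

    Window k covers positions [k*w + 1, (k+1)*w]; every variant belongs
    to exactly one window.  Empty windows report zero count and density
    with NaN quartiles.
    """
    positions = np.asarray(positions)
    maf = np.asarray(maf, dtype=float)
    if positions.size and np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    if positions.size == 0:
        return pd.DataFrame(columns=["window", "start", "end", "count",
                                     "density_per_kb", "maf_q1", "maf_median", "maf_q3"])
    win = (positions - 1) // window_bp
    n_win = int(win.max()) + 1
    rows = []
    for k in range(n_win):
        m = maf[win == k]
        rows.append({
            "window": k, "start": k * window_bp + 1, "end": (k + 1) * window_bp,
            "count": int(m.size),
            "density_per_kb": m.size / (window_bp / 1000.0),
            "maf_q1": float(np.percentile(m, 25)) if m.size else np.nan,
            "maf_median": float(np.percentile(m, 50)) if m.size else np.nan,
            "maf_q3": float(np.percentile(m, 75)) if m.size else np.nan,
        })
    return pd.DataFrame(rows)
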