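"""Exact Li-Stephens haplotype-copying imputation.

Each pre-phased study haplotype is modelled as an imperfect mosaic of
the reference haplotypes: a hidden Markov chain over which reference
haplotype is being copied, with switch intensity rho per base pair and
a per-site copying error epsilon.  The forward-backward algorithm gives
the exact posterior over copied haplotypes at every reference site, and
with it the probability that the study haplotype carries allele B.
Genotype probability triplets for an individual combine its two
haplotype posteriors independently.

This is the exact analogue of the model production imputation engines
approximate with MCMC and state subsetting; at desk scale (a few
hundred haplotypes, tens of thousands of sites) exactness is affordable
and preferable.  Phasing is an input, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from imputefilter.io_formats import (
    MISSING,
    GenotypeProbabilities,
    HaplotypePanel,
    VariantRecord,
)

__all__ = [
    "LSParams",
    "transition_prob",
    "forward_backward",
    "impute_cohort",
]


@dataclass
class LSParams:
    """Copying-model parameters.

    rho_per_bp folds the population-scaled recombination rate and panel
    size into one per-bp switch intensity; epsilon is the per-site
    mismatch (mutation + genotyping) probability.  K limits the number
    of reference haplotypes used as states (None or >= panel size means
    the full panel; correctness over speed at desk scale).
    """

    K: int | None = None
    rho_per_bp: float = 1e-5
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        if self.K is not None and self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must lie in [0, 0.5)")
        if self.rho_per_bp < 0:
            raise ValueError("rho_per_bp must be non-negative")


def transition_prob(distance_bp: float, params: LSParams, k: int
                    ) -> tuple[float, float]:
    """(stay, per-state switch) probabilities across a gap.

    switch-any = 1 - exp(-rho*d); a switch lands uniformly on the K
    states (including the current one), so stay = 1 - switch-any +
    switch-any/K and stay + (K-1)*switch = 1 exactly.
    """
    if distance_bp < 0:
        raise ValueError("distance must be non-negative")
    q = 1.0 - np.exp(-params.rho_per_bp * distance_bp)
    return 1.0 - q + q / k, q / k


def _emissions(ref: np.ndarray, obs: np.ndarray, eps: float) -> np.ndarray:
    """Emission matrix (n_hap, K) for one site: match -> 1-eps, else eps,
    missing observation -> 1."""
    e = np.where(ref[None, :] == obs[:, None], 1.0 - eps, eps)
    e[obs == MISSING] = 1.0
    return e


def forward_backward(observed: np.ndarray, typed_index: np.ndarray,
                     ref: HaplotypePanel, params: LSParams,
                     batch_size: int = 64,
                     dtype: np.dtype = np.float64) -> np.ndarray:
    """Posterior allele-B probability at every reference site.

    ``observed`` holds typed alleles per study haplotype, shape
    (n_hap, n_typed), values {0, 1, MISSING}; ``typed_index`` maps its
    columns into the reference site axis.  Returns (n_hap, n_sites)
    posteriors.  Scaled arithmetic throughout, so sequences of 1e5
    sites do not underflow.
    """
    observed = np.atleast_2d(np.asarray(observed))
    typed_index = np.asarray(typed_index, dtype=int)
    if typed_index.size != observed.shape[1]:
        raise ValueError("typed_index length must match observed columns")
    n_hap = observed.shape[0]
    L = ref.n_sites
    K = ref.n_haplotypes if params.K is None else min(params.K, ref.n_haplotypes)
    H = ref.haplotypes[:K]  # (K, L)
    eps = params.epsilon
    rho = params.rho_per_bp
    pos = ref.positions.astype(np.float64)

    # P(study allele = 1 | copied state k), epsilon-adjusted
    p_allele1 = (H * (1.0 - eps) + (1.0 - H) * eps).astype(dtype)  # (K, L)

    if typed_index.size == 0:
        flat = np.broadcast_to(p_allele1.mean(axis=0), (n_hap, L)).copy()
        return flat

    # Emissions exist only at typed sites; across unobserved stretches
    # the uniform-switch kernel composes exactly
    # (1 - prod(1 - q_g) = 1 - exp(-rho * total distance)), so the
    # recursion only needs one step per typed anchor.  Posteriors at
    # untyped sites follow in closed form from the flanking anchors'
    # forward and backward variables.
    anchors = typed_index
    T = anchors.size
    anchor_pos = pos[anchors]
    q_between = 1.0 - np.exp(-rho * np.diff(anchor_pos))

    out = np.empty((n_hap, L))
    for start in range(0, n_hap, batch_size):
        obs_b = observed[start:start + batch_size]
        B = obs_b.shape[0]
        # forward over anchors; a_fwd[i] includes the emission at anchor i
        a_fwd = np.empty((T, B, K), dtype=dtype)
        a = (np.full((B, K), 1.0 / K)
             * _emissions(H[:, anchors[0]], obs_b[:, 0], eps)).astype(dtype)
        a /= a.sum(axis=1, keepdims=True)
        a_fwd[0] = a
        for i in range(1, T):
            a = (1.0 - q_between[i - 1]) * a + q_between[i - 1] / K
            a = a * _emissions(H[:, anchors[i]], obs_b[:, i], eps).astype(dtype)
            a /= a.sum(axis=1, keepdims=True)
            a_fwd[i] = a
        # backward; d_bwd[i] = emission_i * beta_i, normalized
        d_bwd = np.empty((T, B, K), dtype=dtype)
        d = (_emissions(H[:, anchors[-1]], obs_b[:, -1], eps)
             * np.ones((B, K))).astype(dtype)
        d /= d.sum(axis=1, keepdims=True)
        d_bwd[-1] = d
        for i in range(T - 2, -1, -1):
            b = (1.0 - q_between[i]) * d + q_between[i] / K
            d = b * _emissions(H[:, anchors[i]], obs_b[:, i], eps).astype(dtype)
            d /= d.sum(axis=1, keepdims=True)
            d_bwd[i] = d

        # posteriors at the anchors themselves: gamma ∝ a_fwd ⊙ beta,
        # with beta folded in via d_bwd (a_fwd and d_bwd both contain
        # the anchor emission; divide one copy out through the identity
        # gamma_i ∝ a_fwd[i] ⊙ T(q) d_bwd[i+1])
        for i in range(T):
            if i < T - 1:
                beta = (1.0 - q_between[i]) * d_bwd[i + 1] + q_between[i] / K
            else:
                beta = np.ones((B, K), dtype=dtype)
            gamma = a_fwd[i] * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            out[start:start + B, anchors[i]] = gamma @ p_allele1[:, anchors[i]]

        # untyped segments: before the first anchor, between anchors,
        # after the last anchor
        seg_bounds = [(-1, 0)] + [(i, i + 1) for i in range(T - 1)] + [(T - 1, T)]
        for left, right in seg_bounds:
            lo = anchors[left] + 1 if left >= 0 else 0
            hi = anchors[right] if right < T else L
            sites = np.arange(lo, hi)
            if sites.size == 0:
                continue
            a_seg = a_fwd[left] if left >= 0 else np.full((B, K), 1.0 / K, dtype=dtype)
            d_seg = d_bwd[right] if right < T else np.full((B, K), 1.0 / K, dtype=dtype)
            ql = (1.0 - np.exp(-rho * (pos[sites] - anchor_pos[left]))
                  if left >= 0 else np.zeros(sites.size))
            qr = (1.0 - np.exp(-rho * (anchor_pos[right] - pos[sites]))
                  if right < T else np.zeros(sites.size))
            p_seg = p_allele1[:, sites]  # (K, m)
            # expand gamma_t ∝ [(1-ql)a + ql/K] ⊙ [(1-qr)d + qr/K]
            P_ad = (a_seg * d_seg) @ p_seg
            P_a = a_seg @ p_seg
            P_d = d_seg @ p_seg
            P_1 = p_seg.sum(axis=0)
            cl, cr = 1.0 - ql, 1.0 - qr
            num = (cl * cr * P_ad + cl * (qr / K) * P_a
                   + (ql / K) * cr * P_d + (ql * qr / K ** 2) * P_1)
            S_ad = (a_seg * d_seg).sum(axis=1, keepdims=True)
            den = (cl * cr * S_ad + cl * qr / K + ql * cr / K + ql * qr / K)
            out[start:start + B, sites] = num / den
    return out


def impute_cohort(study_haplotypes: np.ndarray, typed_index: np.ndarray,
                  ref: HaplotypePanel, params: LSParams,
                  samples: list[str] | None = None,
                  batch_size: int = 64,
                  dtype: np.dtype = np.float64) -> GenotypeProbabilities:
    """Impute a cohort of pre-phased individuals at all reference sites.

    ``study_haplotypes`` is (2*n_individuals, n_typed); haplotypes
    (2i, 2i+1) form individual i.  The two haplotype posteriors a, b
    combine independently: p2 = a*b, p1 = a(1-b) + b(1-a),
    p0 = (1-a)(1-b).  Fully deterministic -- no sampling anywhere.
    """
    study_haplotypes = np.asarray(study_haplotypes)
    if study_haplotypes.shape[0] % 2:
        raise ValueError("odd haplotype count: cannot pair into individuals")
    n_ind = study_haplotypes.shape[0] // 2
    post = forward_backward(study_haplotypes, typed_index, ref, params,
                            batch_size=batch_size, dtype=dtype)
    post = post.astype(np.float64)
    a, b = post[0::2], post[1::2]  # (n_ind, L) each
    p2 = a * b
    p1 = a * (1 - b) + b * (1 - a)
    p0 = (1 - a) * (1 - b)
    probs = np.stack([p0, p1, p2], axis=2).transpose(1, 0, 2)  # (L, n_ind, 3)
    if samples is None:
        samples = [f"ind{i:04d}" for i in range(n_ind)]
    typed_set = set(int(i) for i in np.asarray(typed_index))
    variants = [
        VariantRecord(id=str(ref.ids[i]), chrom=ref.chrom, pos=int(ref.positions[i]),
                      allele_a=str(ref.allele_a[i]), allele_b=str(ref.allele_b[i]),
                      source="typed" if i in typed_set else "imputed_only")
        for i in range(ref.n_sites)
    ]
    return GenotypeProbabilities(variants, samples, probs)
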