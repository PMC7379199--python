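"""Genotype QC, VanRaden genomic relationships and single-step H algebra.

The genomic relationship matrix (GRM) follows VanRaden: with dosage x_ij
(count of the second allele), allele frequency p_j and SNP weight d_j,
w_ij = x_ij - 2 p_j and G = W D W' / sum_j 2 p_j (1 - p_j).  Single-step
evaluation combines pedigree and genomic information in one relationship
matrix H whose inverse is A^-1 plus (G^-1 - A22^-1) in the genotyped
block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenotypePanel:
    """Animals x SNPs dosage matrix with its SNP map.

    ``dosages`` is float with NaN for missing calls; the map has one row
    per SNP with columns snp_id, chrom, pos (1-based bp, non-decreasing
    within chromosome).
    """

    ids: list[str]
    dosages: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self):
        self.ids = [str(a) for a in self.ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.snp_map)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.ids)} animals x {len(self.snp_map)} map rows"
            )
        for chrom, g in self.snp_map.groupby("chrom"):
            if not g["pos"].is_monotonic_increasing:
                raise ValueError(f"SNP positions not sorted on chromosome {chrom}")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def allele_frequencies(self) -> np.ndarray:
        """Observed second-allele frequencies among non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_snps(self, keep: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            ids=self.ids,
            dosages=self.dosages[:, keep],
            snp_map=self.snp_map.loc[keep].reset_index(drop=True),
        )


@dataclass
class QcThresholds:
    """SNP quality-control cutoffs."""

    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 0.001


@dataclass
class Grm:
    matrix: np.ndarray
    freqs: np.ndarray
    weights: np.ndarray
    scale: float  # sum_j 2 p_j (1 - p_j)
    ids: list[str] = field(default_factory=list)


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg equilibrium p-value (Pearson chi-square, 1 df).

    Expected genotype counts come from the observed allele frequency; a
    monomorphic SNP has chi-square 0 and p = 1 (it is caught by the MAF
    filter, not here).
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative genotype count")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * n_bb + n_ab) / (2 * n)
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Vectorised HWE p per SNP over integer-valued (hard) genotypes only."""
    hard = np.isfinite(dosages) & (np.mod(dosages, 1) == 0)
    n0 = ((dosages == 0) & hard).sum(axis=0).astype(float)
    n1 = ((dosages == 1) & hard).sum(axis=0).astype(float)
    n2 = ((dosages == 2) & hard).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    n = np.where(n == 0, np.nan, n)
    p = (2 * n2 + n1) / (2 * n)
    chi2 = np.zeros(dosages.shape[1])
    for counts, expect in ((n0, (1 - p) ** 2), (n1, 2 * p * (1 - p)), (n2, p**2)):
        e = n * expect
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 += np.where(e > 0, (counts - e) ** 2 / e, 0.0)
    return stats.chi2.sf(chi2, df=1)


def qc_filter(
    panel: GenotypePanel, thresholds: QcThresholds | None = None
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Drop SNPs failing MAF, call-rate or HWE cutoffs; mean-impute the rest.

    Missing dosages of surviving SNPs are imputed to 2 p_j (which leaves
    the allele frequency unchanged), making the filter idempotent: HWE is
    recomputed from hard genotypes only, so a second pass removes nothing.

    Returns the filtered panel and a per-SNP report with the three test
    values and a ``kept`` flag.
    """
    th = thresholds or QcThresholds()
    X = panel.dosages
    freq = panel.allele_frequencies()
    maf = np.minimum(freq, 1 - freq)
    call_rate = np.isfinite(X).mean(axis=0)
    hwe_p = _hwe_pvalues(X)

    fail_maf = maf < th.maf_min
    fail_cr = call_rate < th.call_rate_min
    fail_hwe = hwe_p < th.hwe_p_min
    keep = ~(fail_maf | fail_cr | fail_hwe)

    report = panel.snp_map.copy()
    report["maf"] = maf
    report["call_rate"] = call_rate
    report["hwe_p"] = hwe_p
    report["fail_maf"] = fail_maf
    report["fail_call_rate"] = fail_cr
    report["fail_hwe"] = fail_hwe
    report["kept"] = keep

    if not keep.any():
        raise ValueError("no SNPs survive QC")

    filtered = panel.subset_snps(np.nonzero(keep)[0])
    X2 = filtered.dosages
    miss = ~np.isfinite(X2)
    if miss.any():
        fill = np.nanmean(X2, axis=0)  # mean dosage = 2 p_j
        X2 = np.where(miss, fill[None, :], X2)
        filtered = GenotypePanel(filtered.ids, X2, filtered.snp_map)
    return filtered, report


def vanraden_g(panel: GenotypePanel, weights: np.ndarray | None = None) -> Grm:
    """VanRaden GRM with optional diagonal SNP weights (initially D = I).

    Frequencies are the observed frequencies among the genotyped animals;
    the scaling constant is sum_j 2 p_j (1 - p_j).
    """
    X = panel.dosages
    if not np.isfinite(X).all():
        raise ValueError("panel has missing dosages; run qc_filter first")
    p = X.mean(axis=0) / 2.0
    d = np.ones(panel.n_snps) if weights is None else np.asarray(weights, dtype=float)
    if d.shape != (panel.n_snps,) or (d <= 0).any():
        raise ValueError("weights must be positive, one per SNP")
    scale = float(np.sum(2.0 * p * (1.0 - p)))
    if scale == 0:
        raise ValueError("all SNPs monomorphic: sum 2pq = 0")
    W = X - 2.0 * p
    G = (W * d) @ W.T / scale
    return Grm(matrix=G, freqs=p, weights=d, scale=scale, ids=list(panel.ids))


def blend_g(G: np.ndarray, A22: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """G* = (1 - alpha) G + alpha A22, the usual invertibility blend."""
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    G = np.asarray(G, dtype=float)
    A22 = np.asarray(A22, dtype=float)
    if G.shape != A22.shape:
        raise ValueError(f"shape mismatch {G.shape} vs {A22.shape}")
    return (1.0 - alpha) * G + alpha * A22


def h_inverse(a_inv: np.ndarray, a22_mat: np.ndarray, g_blended: np.ndarray, genotyped_idx) -> np.ndarray:
    """H^-1 = A^-1 with (G^-1 - A22^-1) added into the genotyped block."""
    gi = np.asarray(genotyped_idx, dtype=np.int64)
    H = np.array(a_inv, dtype=float, copy=True)
    try:
        g_inv = np.linalg.inv(g_blended)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "G is singular; blend it with A22 (blend_g, alpha > 0) before inverting"
        ) from e
    a22_inv = np.linalg.inv(a22_mat)
    H[np.ix_(gi, gi)] += g_inv - a22_inv
    return 0.5 * (H + H.T)


def h_matrix(A: np.ndarray, genotyped_idx, g_blended: np.ndarray) -> np.ndarray:
    """Dense H from its partitioned form (the matrix h_inverse inverts).

    With 1 = ungenotyped, 2 = genotyped:
    H11 = A11 + A12 A22^-1 (G - A22) A22^-1 A21, H12 = A12 A22^-1 G,
    H22 = G.
    """
    n = A.shape[0]
    gi = np.asarray(genotyped_idx, dtype=np.int64)
    oi = np.setdiff1d(np.arange(n), gi)
    A22i = np.linalg.inv(A[np.ix_(gi, gi)])
    B = A[np.ix_(oi, gi)] @ A22i  # regression of ungenotyped on genotyped
    H = np.empty_like(A)
    H[np.ix_(gi, gi)] = g_blended
    H[np.ix_(oi, gi)] = B @ g_blended
    H[np.ix_(gi, oi)] = H[np.ix_(oi, gi)].T
    H[np.ix_(oi, oi)] = A[np.ix_(oi, oi)] + B @ (g_blended - A[np.ix_(gi, gi)]) @ B.T
    return 0.5 * (H + H.T)
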