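"""Single-step GWAS: backsolved SNP effects, window variances, p-values.

Genomic breeding values (GEBV) are predicted under the H-matrix animal
model; SNP effects are then backsolved as beta = D W'(W D W')^-1 a_g.
SNP weights can be refined iteratively (d_j proportional to
beta_j^2 2 p_j q_j).  The proportion of additive genetic variance explained
by a window of consecutive SNPs within a fixed span is
var(sum_j W_j beta_j) / sigma_a2 x 100%, computed over the genotyped
animals with overlapping windows (one window anchored at every SNP).
Frequentist p-values use the single unweighted run (D = I).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .genomic import GenotypePanel, blend_g, h_matrix, vanraden_g
from .mixed import AnimalModel, VarianceComponents, build_design
from .pedigree import Pedigree, nrm

logger = logging.getLogger(__name__)


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def backsolve_snp_effects(
    a_hat_g: np.ndarray,
    W: np.ndarray,
    d: np.ndarray | None = None,
    pseudo_inverse: bool = False,
    relationship: tuple[np.ndarray, float] | None = None,
) -> np.ndarray:
    """SNP effects from genotyped-animal GEBV: beta = D W'(W D W')^-1 a_g.

    ``W`` is the centered dosage matrix of the genotyped animals (rows) by
    SNPs (columns); ``d`` the diagonal SNP weights.  Uniform rescaling of d
    cancels.  Centering on observed frequencies makes W D W' itself
    singular (its rows sum to zero), so either pass ``relationship`` as a
    (blended G*, sum 2pq) pair whose product stands in for W D W' -- the
    blended-G path used by the MME -- or set ``pseudo_inverse`` for the
    minimum-norm solution; otherwise a singular W D W' raises.
    """
    n_g, m = W.shape
    d = np.ones(m) if d is None else np.asarray(d, dtype=float)
    WD = W * d
    if relationship is not None:
        gstar, scale = relationship
        T = gstar * scale
    else:
        T = WD @ W.T
    if pseudo_inverse:
        t = np.linalg.pinv(T) @ a_hat_g
    else:
        try:
            ct = linalg.cholesky(T, lower=True)
            t = linalg.cho_solve((ct, True), a_hat_g)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "W D W' is singular; pass pseudo_inverse=True or blend G"
            ) from None
    return d * (W.T @ t)


def refine_weights(beta: np.ndarray, freqs: np.ndarray, floor_frac: float = 1e-8) -> np.ndarray:
    """Wang-style SNP weights d_j ~ beta_j^2 2 p_j (1-p_j), sum rescaled to m.

    All-zero effects give uniform weights; weights are floored at
    ``floor_frac * max(d)`` to avoid exact zeros.
    """
    beta = np.asarray(beta, dtype=float)
    p = np.asarray(freqs, dtype=float)
    d = beta**2 * 2.0 * p * (1.0 - p)
    m = d.size
    if not d.any():
        return np.ones(m)
    d = np.maximum(d, floor_frac * d.max())
    return d * (m / d.sum())


def window_variance(
    beta: np.ndarray,
    W: np.ndarray,
    snp_map: pd.DataFrame,
    sigma_a2: float,
    window_bp: int = 100_000,
) -> pd.DataFrame:
    """Per-window percentage of additive genetic variance.

    One (overlapping) window is anchored at every SNP j; members are the
    consecutive SNPs on the same chromosome with position in
    [pos_j, pos_j + window_bp).  The window's statistic is the variance,
    over genotyped animals, of the summed member-SNP contributions
    W beta, as a percentage of sigma_a2.
    """
    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos"].to_numpy(dtype=np.int64)
    order_ok = True
    for c in np.unique(chrom):
        pc = pos[chrom == c]
        if np.any(np.diff(pc) < 0):
            order_ok = False
    if not order_ok:
        raise ValueError("SNP map must be sorted by (chrom, pos)")
    m = len(snp_map)
    rows = []
    for c in np.unique(chrom):
        sel = np.nonzero(chrom == c)[0]
        pc = pos[sel]
        ends = np.searchsorted(pc, pc + window_bp, side="left")
        # cumulative contributions make each window an O(n_g) slice-sum
        Wc = W[:, sel]
        bc = beta[sel]
        contrib = Wc * bc
        csum = np.cumsum(contrib, axis=1)
        for j in range(len(sel)):
            k = ends[j]
            g = csum[:, k - 1] - (csum[:, j - 1] if j > 0 else 0.0)
            pct = float(np.var(g, ddof=1) / sigma_a2 * 100.0) if sigma_a2 > 0 else 0.0
            rows.append(
                {
                    "chrom": c,
                    "start_bp": int(pc[j]),
                    "end_bp": int(pc[j]) + window_bp,
                    "n_snps": int(k - j),
                    "first_snp": int(sel[j]),
                    "last_snp": int(sel[k - 1]),
                    "variance_pct": pct,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class QtlRegion:
    chrom: object
    start_bp: int
    end_bp: int
    n_snps: int
    max_variance_pct: float


def qtl_regions(windows: pd.DataFrame, threshold_pct: float = 5.0) -> list[QtlRegion]:
    """Merge overlapping super-threshold windows into QTL regions.

    A region's variance is the maximum member-window percentage (ties
    broken by lowest start position via the scan order); its SNP count is
    the number of consecutive map SNPs it spans.
    """
    hits = windows[windows["variance_pct"] > threshold_pct]
    regions: list[QtlRegion] = []
    for c, g in hits.groupby("chrom", sort=True):
        g = g.sort_values(["start_bp", "end_bp"]).reset_index(drop=True)
        cur = None
        for _, w in g.iterrows():
            if cur is not None and w["start_bp"] < cur["end_bp"]:  # half-open overlap
                cur["end_bp"] = max(cur["end_bp"], int(w["end_bp"]))
                cur["last_snp"] = max(cur["last_snp"], int(w["last_snp"]))
                if w["variance_pct"] > cur["max_pct"]:
                    cur["max_pct"] = float(w["variance_pct"])
            else:
                if cur is not None:
                    regions.append(_region_from(cur, c))
                cur = {
                    "start_bp": int(w["start_bp"]),
                    "end_bp": int(w["end_bp"]),
                    "first_snp": int(w["first_snp"]),
                    "last_snp": int(w["last_snp"]),
                    "max_pct": float(w["variance_pct"]),
                }
        if cur is not None:
            regions.append(_region_from(cur, c))
    return regions


def _region_from(cur: dict, chrom) -> QtlRegion:
    return QtlRegion(
        chrom=chrom,
        start_bp=cur["start_bp"],
        end_bp=cur["end_bp"],
        n_snps=cur["last_snp"] - cur["first_snp"] + 1,
        max_variance_pct=cur["max_pct"],
    )


def var_beta(
    W: np.ndarray,
    d: np.ndarray,
    var_a_hat: np.ndarray,
    relationship: tuple[np.ndarray, float] | None = None,
) -> np.ndarray:
    """Sampling variances of backsolved SNP effects.

    var(beta) = diag of D W'(W D W')^-1 Var(a_g) (W D W')^-1 W D, where
    Var(a_g) is the variance of the GEBV estimator (G sigma_a2 minus the
    prediction error variance).  ``relationship`` substitutes the blended
    (G*, sum 2pq) product for W D W' exactly as in the backsolve.  Small
    negative diagonals from numerical error are clipped to zero and
    logged.
    """
    if relationship is not None:
        gstar, scale = relationship
        T = gstar * scale
    else:
        T = (W * d) @ W.T
    Q = d[:, None] * np.linalg.solve(T, W).T  # rows: D W' (W D W')^-1
    v = np.einsum("ij,jk,ik->i", Q, var_a_hat, Q)
    if (v < 0).any():
        logger.info("clipped %d negative SNP-effect variances to 0", int((v < 0).sum()))
        v = np.clip(v, 0.0, None)
    return v


def snp_pvalues(beta: np.ndarray, var_b: np.ndarray) -> np.ndarray:
    """p_j = 2 (1 - Phi(|beta_j| / sd_j)); sd_j = 0 gives p = 1 with a warning."""
    if (np.asarray(var_b) < 0).any():
        raise ValueError("negative SNP-effect variance")
    sd = np.sqrt(var_b)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} SNPs have zero effect SD; p set to 1")
    z = np.zeros_like(beta)
    np.divide(np.abs(beta), sd, out=z, where=~zero)
    p = 2.0 * stats.norm.sf(z)
    return np.clip(p, 1e-300, 1.0)


# ----------------------------------------------------------------------
# the full pipeline
# ----------------------------------------------------------------------

@dataclass
class SsgwasResults:
    """Per-SNP effects, window variances and QTL regions from one ssGWAS run."""

    snp_table: pd.DataFrame
    windows: pd.DataFrame
    regions: pd.DataFrame
    components: VarianceComponents
    gebv: pd.DataFrame
    bonferroni: float
    n_weight_iters: int
    weights: np.ndarray

    def summary(self) -> str:
        top = self.windows.loc[self.windows["variance_pct"].idxmax()]
        n_sig = int((self.snp_table["pvalue"] < self.bonferroni).sum())
        lines = [
            "Single-step GWAS results",
            "=" * 46,
            f"SNPs tested:          {len(self.snp_table)}",
            f"weight refinements:   {self.n_weight_iters}",
            f"h^2 (genome-based):   {self.components.h2:.3f} (SE {self.components.se_h2:.3f})",
            f"Bonferroni threshold: {self.bonferroni:.3e}",
            f"genome-wide significant SNPs: {n_sig}",
            f"top window: chrom {top['chrom']} at {int(top['start_bp'])} bp "
            f"({top['variance_pct']:.2f}% of genetic variance)",
            f"QTL regions over 5%:  {len(self.regions)}",
        ]
        return "\n".join(lines)

    def plot_manhattan(self, path=None, value: str = "variance_pct"):
        """Manhattan plot of window variance percentages (or -log10 p)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 3))
        if value == "variance_pct":
            tab, y, lab = self.windows, self.windows["variance_pct"], "% genetic variance"
        else:
            tab, y, lab = self.snp_table, -np.log10(self.snp_table["pvalue"]), "-log10 p"
        offset, ticks = 0.0, []
        for i, (c, g) in enumerate(tab.groupby("chrom", sort=True)):
            x = g["start_bp" if "start_bp" in g else "pos"].to_numpy(float) + offset
            ax.scatter(x, y[g.index], s=4, color=f"C{i % 2}")
            ticks.append((x.min() + x.max()) / 2)
            offset = x.max()
        ax.set_ylabel(lab)
        ax.set_xlabel("chromosome")
        ax.set_xticks(ticks, [str(c) for c in tab["chrom"].unique()])
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


class SingleStepGWAS:
    """ssGWAS model: phenotypes + pedigree + genotyped-sire panel.

    Parameters
    ----------
    phenotypes : DataFrame with animal_id, contemporary group, age and trait.
    pedigree : Pedigree over all animals.
    panel : QC'd GenotypePanel of the genotyped animals.
    variance_components : optional (sigma_a2, sigma_e2); estimated by
        REML under the unweighted H model when not supplied.
    alpha_blend : G* = (1 - alpha) G + alpha A22 blending fraction.
    n_weight_iters : number of SNP-weight refinements for the effect/window
        pass (p-values always come from the unweighted single run).
    """

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        pedigree: Pedigree,
        panel: GenotypePanel,
        trait: str,
        cg_col: str = "cg",
        age_col: str = "age",
        animal_col: str = "animal_id",
        variance_components: tuple[float, float] | None = None,
        alpha_blend: float = 0.05,
        n_weight_iters: int = 2,
        window_bp: int = 100_000,
        threshold_pct: float = 5.0,
        bonferroni_alpha: float = 0.05,
    ):
        data = phenotypes[np.isfinite(phenotypes[trait].to_numpy(dtype=float))]
        self.X, self.column_names, self.rec_idx = build_design(
            data, cg_col, age_col, animal_col, pedigree
        )
        self.y = data[trait].to_numpy(dtype=float)
        self.pedigree = pedigree
        self.panel = panel
        self.trait = trait
        self.variance_components = variance_components
        self.alpha_blend = alpha_blend
        self.n_weight_iters = n_weight_iters
        self.window_bp = window_bp
        self.threshold_pct = threshold_pct
        self.bonferroni_alpha = bonferroni_alpha
        self.gen_idx = pedigree.indices(panel.ids)

    # -- single-step BLUP at fixed components (GLS form over records) ----
    def _blup(self, H: np.ndarray, su2: float, se2: float, want_var: bool = False):
        Hpp = H[np.ix_(self.rec_idx, self.rec_idx)]
        Hgp = H[np.ix_(self.gen_idx, self.rec_idx)]
        V = su2 * Hpp + se2 * np.eye(len(self.y))
        cf = linalg.cho_factor(V, lower=True)
        Vx = linalg.cho_solve(cf, self.X)
        C = self.X.T @ Vx
        b = np.linalg.solve(C, Vx.T @ self.y)
        py = linalg.cho_solve(cf, self.y - self.X @ b)
        a_g = su2 * (Hgp @ py)
        if not want_var:
            return b, a_g, None
        # Var(a_hat_g) = su2^2 Hgp P Hpg  (== G* su2 - PEV)
        PH = linalg.cho_solve(cf, Hgp.T) - Vx @ np.linalg.solve(C, Vx.T @ Hgp.T)
        var_a = su2**2 * (Hgp @ PH)
        return b, a_g, var_a

    def fit(self) -> SsgwasResults:
        ped, panel = self.pedigree, self.panel
        A = nrm(ped).matrix
        A22 = A[np.ix_(self.gen_idx, self.gen_idx)]
        m = panel.n_snps

        def h_for(weights):
            grm = vanraden_g(panel, weights)
            Gstar = blend_g(grm.matrix, A22, self.alpha_blend)
            return h_matrix(A, self.gen_idx, Gstar), grm, Gstar

        # unweighted run: components, p-values
        d0 = np.ones(m)
        H0, grm0, Gstar0 = h_for(d0)
        if self.variance_components is None:
            vc = AnimalModel(self.y, self.X, H0, self.rec_idx).fit().vc
        else:
            su2, se2 = self.variance_components
            vc = VarianceComponents(
                sigma_u2=su2, sigma_e2=se2, h2=su2 / (su2 + se2),
                se_sigma_u2=float("nan"), se_sigma_e2=float("nan"), se_h2=float("nan"),
                loglik=float("nan"), converged=True, n_iter=0,
            )
        su2, se2 = vc.sigma_u2, vc.sigma_e2
        W = panel.dosages - 2.0 * grm0.freqs

        _, a_g0, var_a0 = self._blup(H0, su2, se2, want_var=True)
        beta0 = backsolve_snp_effects(a_g0, W, d0, relationship=(Gstar0, grm0.scale))
        vb = var_beta(W, d0, var_a0, relationship=(Gstar0, grm0.scale))
        pvals = snp_pvalues(beta0, vb)

        # weighted passes for effects and windows
        beta, d = beta0, d0
        for _ in range(self.n_weight_iters):
            d = refine_weights(beta, grm0.freqs)
            H, grm, Gstar = h_for(d)
            _, a_g, _ = self._blup(H, su2, se2)
            beta = backsolve_snp_effects(a_g, W, d, relationship=(Gstar, grm.scale))
            # under blending W beta reconstructs (1-alpha) of the marker part
            recon = float(np.max(np.abs(W @ beta - a_g)))
            logger.debug("GEBV reconstruction residual %.2e", recon)

        windows = window_variance(beta, W, panel.snp_map, su2, self.window_bp)
        regions = qtl_regions(windows, self.threshold_pct)
        snp_table = pd.DataFrame(
            {
                "chrom": panel.snp_map["chrom"],
                "pos": panel.snp_map["pos"],
                "snp_id": panel.snp_map["snp_id"],
                "beta": beta,
                "sd_beta": np.sqrt(vb),
                "pvalue": pvals,
                "weight": d,
            }
        ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        regions_df = pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start_bp": r.start_bp,
                    "end_bp": r.end_bp,
                    "n_snps": r.n_snps,
                    "max_variance_pct": r.max_variance_pct,
                }
                for r in regions
            ],
            columns=["chrom", "start_bp", "end_bp", "n_snps", "max_variance_pct"],
        )
        gebv = pd.DataFrame({"animal_id": panel.ids, "gebv": a_g0})
        return SsgwasResults(
            snp_table=snp_table,
            windows=windows.sort_values(["chrom", "start_bp"], kind="stable").reset_index(drop=True),
            regions=regions_df,
            components=vc,
            gebv=gebv,
            bonferroni=bonferroni_threshold(m, self.bonferroni_alpha),
            n_weight_iters=self.n_weight_iters,
            weights=d,
        )


def run_ssgwas(
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    panel: GenotypePanel,
    trait: str,
    n_weight_iters: int = 2,
    **kwargs,
) -> SsgwasResults:
    """Functional entry point over :class:`SingleStepGWAS`."""
    return SingleStepGWAS(
        phenotypes, pedigree, panel, trait, n_weight_iters=n_weight_iters, **kwargs
    ).fit()
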