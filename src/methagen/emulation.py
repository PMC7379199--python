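"""Study-scale simulation studies over the full pipeline.

Each function here runs one canned experiment that emulates the analysed
fattening population at desk scale: generate a sire-progeny population
under stated truth, run the corresponding estimation path, and return the
estimate(s).  They are used both by the test suite and by the
reproduction script.

Problem sizes (about 2,000 phenotyped progeny of 200-334 genotyped sires,
2,000-3,000 SNPs) are chosen so a full study runs in minutes on one core
while keeping the estimators' sampling error small relative to the
quantities checked.
"""

from __future__ import annotations

import numpy as np

from .genomic import blend_g, h_matrix, vanraden_g
from .gwas import run_ssgwas
from .mixed import AnimalModel, BivariateAnimalModel
from .pedigree import nrm
from .simulate import PopulationConfig, TraitSpec, simulate_pedigree, simulate_phenotypes, simulate_population
from .traits import predict_ch4s

#: Generative truth for predicted daily methane (L/day): additive and
#: residual variances of the emulated population, pedigree-based
#: heritability 148.3 / (148.3 + 102.8) = 0.59.
CH4_TRUTH = TraitSpec(251.3, 148.3, 102.8, cg_sd=15.0, age_slope=0.05)

#: Dry matter intake (kg/day) truth: h2 = 0.24 / 0.42 = 0.57, total
#: phenotypic SD ~0.78 including the contemporary-group effect.
DMI_TRUTH = TraitSpec(8.96, 0.24, 0.18, cg_sd=0.43, age_slope=0.002)


def ch4s_population_mean(dmi_mean: float = 8.96, dmi_sd: float = 0.78) -> float:
    """Mean CH4S implied by a DMI distribution via the quadratic moment identity.

    For CH4S = a + b DMI + c DMI^2, E[CH4S] = a + b mu + c (mu^2 + sigma^2)
    exactly, whatever the DMI distribution.
    """
    from .traits import CH4S_COEF

    return float(
        CH4S_COEF["intercept"]
        + CH4S_COEF["DMI"] * dmi_mean
        + CH4S_COEF["DMI2"] * (dmi_mean**2 + dmi_sd**2)
    )


def pedigree_h2_recovery(
    n_reps: int = 12,
    seed: int = 1,
    n_sires: int = 334,
    progeny_per_sire: int = 6,
    trait: TraitSpec = CH4_TRUTH,
) -> np.ndarray:
    """Replicate REML heritability estimates under the pedigree animal model.

    Each replicate simulates ~2,000 progeny with the stated truth and fits
    single-trait AI-REML with the numerator relationship matrix.
    """
    out = []
    for r in range(n_reps):
        cfg = PopulationConfig(
            n_sires=n_sires,
            progeny_per_sire=progeny_per_sire,
            n_cg=150,
            n_chromosomes=1,
            n_snps_per_chrom=10,
            traits={"CH4": trait},
            seed=seed * 10_000 + r,
        )
        ped, meta = simulate_pedigree(cfg)
        phen, _ = simulate_phenotypes(ped, meta, cfg, np.random.default_rng(cfg.seed))
        out.append(AnimalModel.from_dataframe(phen, "CH4", ped).fit().h2)
    return np.array(out)


def genomic_h2_recovery(
    n_reps: int = 10,
    seed: int = 1,
    n_sires: int = 300,
    progeny_per_sire: int = 7,
    h2_true: float = 0.54,
    phenotypic_var: float = 251.1,
    m_snps: int = 3000,
) -> np.ndarray:
    """Replicate REML heritability under the single-step H model.

    Only sires are genotyped; the genetic architecture is fully genomic
    (breeding values are sums of SNP effects gene-dropped through the
    pedigree, calibrated to the target additive variance).
    """
    su2 = h2_true * phenotypic_var
    se2 = (1.0 - h2_true) * phenotypic_var
    out = []
    for r in range(n_reps):
        cfg = PopulationConfig(
            n_sires=n_sires,
            progeny_per_sire=progeny_per_sire,
            n_cg=150,
            n_chromosomes=3,
            n_snps_per_chrom=m_snps // 3,
            chrom_length_bp=100_000_000,
            traits={"CH4": TraitSpec(251.3, su2, se2, cg_sd=15.0, age_slope=0.05)},
            marker_variance_fraction=1.0,
            seed=seed * 10_000 + 5_000 + r,
        )
        pop = simulate_population(cfg)
        ped, panel = pop["pedigree"], pop["panel"]
        A = nrm(ped).matrix
        gi = ped.indices(panel.ids)
        gstar = blend_g(vanraden_g(panel).matrix, A[np.ix_(gi, gi)], 0.05)
        H = h_matrix(A, gi, gstar)
        out.append(AnimalModel.from_dataframe(pop["phenotypes"], "CH4", ped, kinship=H).fit().h2)
    return np.array(out)


def dmi_ch4s_genetic_correlation(seed: int = 1, n_sires: int = 250, progeny_per_sire: int = 8):
    """Bivariate REML genetic correlation between DMI and record-wise CH4S.

    DMI is simulated under the animal model; CH4S is computed for every
    record with the quadratic prediction equation, so the two traits share
    a near-linear deterministic map and their genetic correlation is ~1.
    """
    cfg = PopulationConfig(
        n_sires=n_sires,
        progeny_per_sire=progeny_per_sire,
        n_cg=50,
        n_chromosomes=1,
        n_snps_per_chrom=10,
        traits={"DMI": DMI_TRUTH},
        seed=seed * 10_000 + 777,
    )
    ped, meta = simulate_pedigree(cfg)
    phen, _ = simulate_phenotypes(ped, meta, cfg, np.random.default_rng(cfg.seed))
    phen["CH4S"] = predict_ch4s(phen["DMI"].to_numpy())
    return BivariateAnimalModel.from_dataframe(phen, ("DMI", "CH4S"), ped).fit()


def qtl_localization_run(seed: int, qtl_fraction: float = 0.3):
    """One ssGWAS run on a population with a single QTL on chromosome 1.

    Returns (top window row, true QTL dict) at the ~2,000-progeny,
    2,000-SNP scale with two weight-refinement iterations.
    """
    cfg = PopulationConfig(
        n_sires=200,
        progeny_per_sire=10,
        n_cg=40,
        n_chromosomes=2,
        n_snps_per_chrom=1000,
        chrom_length_bp=50_000_000,
        traits={"CH4": CH4_TRUTH},
        qtl_spec=[(1, 25_000_000, qtl_fraction)],
        seed=seed,
    )
    pop = simulate_population(cfg)
    res = run_ssgwas(
        pop["phenotypes"], pop["pedigree"], pop["panel"], "CH4",
        variance_components=(CH4_TRUTH.sigma_u2, CH4_TRUTH.sigma_e2),
    )
    top = res.windows.loc[res.windows["variance_pct"].idxmax()]
    return top, pop["truth"].qtls[0]


def null_window_max(seed: int) -> float:
    """Largest window variance percentage under a purely polygenic truth."""
    cfg = PopulationConfig(
        n_sires=200,
        progeny_per_sire=10,
        n_cg=40,
        n_chromosomes=2,
        n_snps_per_chrom=1000,
        chrom_length_bp=50_000_000,
        traits={"CH4": CH4_TRUTH},
        seed=seed,
    )
    pop = simulate_population(cfg)
    res = run_ssgwas(
        pop["phenotypes"], pop["pedigree"], pop["panel"], "CH4",
        variance_components=(CH4_TRUTH.sigma_u2, CH4_TRUTH.sigma_e2),
    )
    return float(res.windows["variance_pct"].max())


def null_pvalues(seed: int = 1, m_snps: int = 2000) -> np.ndarray:
    """Per-SNP p-values from an unweighted run under the null (no QTL, no LD)."""
    cfg = PopulationConfig(
        n_sires=150,
        progeny_per_sire=8,
        n_cg=20,
        n_chromosomes=2,
        n_snps_per_chrom=m_snps // 2,
        chrom_length_bp=50_000_000,
        target_ld_r2_at_100kbp=0.0,
        traits={"CH4": CH4_TRUTH},
        seed=seed * 10_000 + 99,
    )
    pop = simulate_population(cfg)
    res = run_ssgwas(
        pop["phenotypes"], pop["pedigree"], pop["panel"], "CH4",
        variance_components=(CH4_TRUTH.sigma_u2, CH4_TRUTH.sigma_e2),
        n_weight_iters=0,
    )
    return res.snp_table["pvalue"].to_numpy()
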