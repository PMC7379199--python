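"""Synthetic sire-progeny populations for testing the analysis pipeline.

The generator emulates a progeny-testing design in fattening cattle:
genotyped sires, each mated to distinct unrelated dams, producing
phenotyped but ungenotyped steer progeny raised in contemporary groups
(year-step-station-herd classes).  It produces

* a two-tier pedigree (optionally with extra founder generations),
* LD-structured genotypes: founder haplotypes from a first-order Markov
  chain along each chromosome, calibrated so the mean r^2 between SNPs
  ~100 kbp apart hits a target, then gene-dropping with Haldane
  recombination at 1 cM per Mbp,
* multi-trait phenotypes under the same animal model the analysis fits:
  phenotype = contemporary-group effect + age covariate + breeding value
  + residual, with breeding values gene-dropped (Mendelian sampling
  variance halved per known parent) and optional marker/QTL architecture,
* longitudinal fattening records (8-weekly weighings, individual
  concentrate intake, herd-unit-averaged roughage intake) from which the
  trait engine re-derives the base traits.

Trait defaults emulate a Japanese Black steer fattening population
(DMI ~ 8.96 +/- 0.78 kg/day, predicted methane ~ 251 L/day with additive
and residual variances 148.3 / 102.8, etc.); the contemporary-group effect
SD is chosen so the total phenotypic SD matches the same population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomic import GenotypePanel
from .pedigree import Pedigree, inbreeding
from .traits import predict_methane, summarize_fattening


@dataclass
class TraitSpec:
    """Generative parameters of one directly simulated trait."""

    mean: float
    sigma_u2: float
    sigma_e2: float
    cg_sd: float = 0.0
    age_slope: float = 0.0

    @property
    def h2(self) -> float:
        return self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)


#: Direct-trait defaults for the methane-related traits (study-scale
#: means/variances; cg_sd set so total phenotypic SD matches the source
#: population's printed SD).
DEFAULT_TRAITS: dict[str, TraitSpec] = {
    "DMI": TraitSpec(8.96, 0.24, 0.18, cg_sd=0.43, age_slope=0.002),
    "CH4": TraitSpec(251.3, 148.3, 102.8, cg_sd=15.0, age_slope=0.05),
    "CH4S": TraitSpec(297.1, 181.6, 136.7, cg_sd=11.8, age_slope=0.05),
    "CH4_per_DMI": TraitSpec(27.5, 0.61, 0.42, cg_sd=0.64, age_slope=0.003),
    "MCF": TraitSpec(5.96, 0.03, 0.02, cg_sd=0.18, age_slope=0.0005),
}

#: Base-trait defaults for record-level simulation.  DMI follows the study
#: population; BW, DG, TDN and Rrate are plausible stand-ins (their real
#: distributions are not published with the trait table).
BASE_TRAIT_DEFAULTS: dict[str, TraitSpec] = {
    "BW": TraitSpec(600.0, 0.57 * 40.0**2, 0.43 * 40.0**2, cg_sd=10.0, age_slope=0.2),
    "DG": TraitSpec(0.85, 0.57 * 0.1**2, 0.43 * 0.1**2, cg_sd=0.02, age_slope=0.0),
    "DMI": TraitSpec(8.96, 0.24, 0.18, cg_sd=0.43, age_slope=0.002),
    "TDN": TraitSpec(72.0, 0.3 * 2.0**2, 0.7 * 2.0**2, cg_sd=0.5, age_slope=0.0),
    "Rrate": TraitSpec(22.8, 0.3 * 5.0**2, 0.7 * 5.0**2, cg_sd=1.0, age_slope=0.0),
}

#: Weighing / intake occasions (weeks on test).
WEEK_SCHEDULE = (1, 9, 17, 25, 33, 41, 49, 52)

#: Diet composition: total digestible nutrients of concentrate and roughage.
TDN_CONCENTRATE = 73.3
TDN_ROUGHAGE = 54.0


@dataclass
class PopulationConfig:
    """Study-design parameters of the simulated population.

    Defaults follow the emulated progeny-testing design: 362 genotyped
    sires with ~13 phenotyped ungenotyped steer progeny each, 348
    contemporary groups from an 11 years x 10 steps x 2 stations x 3 herds
    layout, LD of r^2 = 0.2 at 100 kbp, and a uniform post-QC MAF
    spectrum.  SNP density is a desk-scale default; the real array is far
    denser.
    """

    n_sires: int = 362
    progeny_per_sire: int = 13
    n_cg: int = 348
    cg_factors: tuple[int, int, int, int] = (11, 10, 2, 3)
    n_chromosomes: int = 29
    n_snps_per_chrom: int = 200
    chrom_length_bp: int = 100_000_000
    target_ld_r2_at_100kbp: float = 0.2
    ld_ref_bp: int = 100_000
    maf_min: float = 0.05
    traits: dict[str, TraitSpec] = field(default_factory=lambda: dict(DEFAULT_TRAITS))
    genetic_corr: np.ndarray | None = None
    residual_corr: np.ndarray | None = None
    qtl_spec: list[tuple[int, int, float]] = field(default_factory=list)
    marker_variance_fraction: float = 0.0  # polygenic fraction routed through all SNPs
    calibrate_genetic_variance: bool = True
    age_mean: float = 273.0  # days; test begins at ~9.1 months
    age_sd: float = 15.0
    unit_size: int = 13  # steers per roughage herd unit
    seed: int = 2020

    def __post_init__(self):
        if self.n_sires < 1 or self.progeny_per_sire < 1:
            raise ValueError("n_sires and progeny_per_sire must be >= 1")
        if not 0 <= self.target_ld_r2_at_100kbp <= 0.95:
            raise ValueError("infeasible LD target (must be in [0, 0.95])")
        total = sum(f for *_pos, f in self.qtl_spec)
        if total > 1 + 1e-12 or self.marker_variance_fraction + total > 1 + 1e-12:
            raise ValueError("QTL + marker variance fractions must sum to <= 1")
        for name, corr in (("genetic_corr", self.genetic_corr), ("residual_corr", self.residual_corr)):
            if corr is not None:
                corr = np.asarray(corr, dtype=float)
                if not np.allclose(corr, corr.T) or np.linalg.eigvalsh(corr).min() < -1e-8:
                    raise ValueError(f"{name} must be symmetric positive semidefinite")


@dataclass
class SimTruth:
    """Ground truth of one simulated population."""

    true_bv: pd.DataFrame  # animals x traits
    components: dict[str, TraitSpec]
    qtls: list[dict]
    founder_haplotypes: np.ndarray | None = None
    all_dosages: GenotypePanel | None = None


# ----------------------------------------------------------------------
# pedigree
# ----------------------------------------------------------------------

def simulate_pedigree(config: PopulationConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Two-tier pedigree: founder sires and dams, one dam per mating.

    Returns the pedigree and a metadata table flagging the genotyped
    animals (sires) and phenotyped animals (steer progeny).
    """
    n_s, k = config.n_sires, config.progeny_per_sire
    sires = [f"S{i + 1:04d}" for i in range(n_s)]
    dams = [f"D{i + 1:05d}" for i in range(n_s * k)]
    steers = [f"P{i + 1:05d}" for i in range(n_s * k)]
    triples = [(a, "0", "0") for a in sires + dams]
    for j, p in enumerate(steers):
        triples.append((p, sires[j // k], dams[j]))
    ped = Pedigree.from_triples(triples)
    meta = pd.DataFrame(
        {
            "animal_id": sires + dams + steers,
            "role": ["sire"] * n_s + ["dam"] * len(dams) + ["steer"] * len(steers),
        }
    )
    meta["genotyped"] = meta["role"] == "sire"
    meta["phenotyped"] = meta["role"] == "steer"
    return ped, meta


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------

def _snp_map(config: PopulationConfig) -> pd.DataFrame:
    rows = []
    m_c = config.n_snps_per_chrom
    spacing = config.chrom_length_bp / m_c
    for c in range(1, config.n_chromosomes + 1):
        for j in range(m_c):
            rows.append((f"snp{c}_{j + 1}", c, int(round((j + 0.5) * spacing)) + 1))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


def _transition(c: float, p1: float, p2: float) -> tuple[float, float, float, float]:
    """Achieved correlation and marginal for a clipped binary transition.

    The chain moves by P(x2=1 | x1) = clip(p2 + c (x1 - p1)); returns
    (corr, realized marginal, prob1, prob0).
    """
    prob1 = min(max(p2 + c * (1.0 - p1), 0.0), 1.0)
    prob0 = min(max(p2 - c * p1, 0.0), 1.0)
    m2 = p1 * prob1 + (1.0 - p1) * prob0
    denom = np.sqrt(p1 * (1.0 - p1) * m2 * (1.0 - m2))
    corr = (p1 * prob1 - p1 * m2) / denom if denom > 0 else 0.0
    return corr, m2, prob1, prob0


def _solve_transition(r_target: float, p1: float, p2: float) -> tuple[float, float]:
    """Bisect the transition slope so the achieved correlation hits r_target.

    Clipping of the conditional probability attenuates the correlation, so
    the slope is solved against the exact achieved value; returns
    (slope, realized marginal).  Unreachable targets saturate.
    """
    lo, hi = 0.0, 1.0
    if _transition(hi, p1, p2)[0] < r_target:
        return hi, _transition(hi, p1, p2)[1]
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _transition(mid, p1, p2)[0] < r_target:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    return c, _transition(c, p1, p2)[1]


def _chain_slopes(p, chrom, pos, kappa, t, ld_ref):
    """Transition slopes, realized marginals and achieved step correlations.

    Step correlation targets are t^(kappa * gap / (2 * ld_ref)); each slope
    is solved against the exactly computable achieved correlation, which
    saturates when the neighbouring allele frequencies are too different
    for the requested correlation to exist.
    """
    m = len(p)
    slopes = np.zeros(m)
    marg = p.astype(float).copy()
    step_corr = np.ones(m)  # corr between locus j-1 and j; 1 sentinel at chain starts
    for j in range(1, m):
        if chrom[j] != chrom[j - 1]:
            continue
        r = t ** (kappa * (pos[j] - pos[j - 1]) / (2.0 * ld_ref))
        slopes[j], marg[j] = _solve_transition(r, marg[j - 1], p[j])
        step_corr[j] = _transition(slopes[j], marg[j - 1], p[j])[0]
    return slopes, marg, step_corr


def _mean_r2_at_ref(step_corr, chrom, pos, ld_ref):
    """Analytic mean r^2 between locus pairs ~ld_ref apart under the chain."""
    with np.errstate(divide="ignore"):
        logs = np.log(np.maximum(step_corr, 1e-300))
    logs[0] = 0.0
    starts = np.concatenate([[True], chrom[1:] != chrom[:-1]])
    logs[starts] = 0.0
    cum = np.cumsum(logs)
    vals = []
    for c in np.unique(chrom):
        sel = np.nonzero(chrom == c)[0]
        pc = pos[sel]
        for jj, j in enumerate(sel):
            k = np.searchsorted(pc, pc[jj] + ld_ref, side="left")
            if k < len(sel) and pc[k] - pc[jj] <= 1.5 * ld_ref:
                vals.append(np.exp(2.0 * (cum[sel[k]] - cum[j])))
    return float(np.mean(vals)) if vals else 0.0


def _founder_haplotypes(n_hap: int, snp_map: pd.DataFrame, config: PopulationConfig, rng) -> np.ndarray:
    """Markov-chain haplotypes with calibrated LD decay.

    A first-order Markov chain along each chromosome induces correlation
    products over distance; the decay exponent is calibrated (by bisection
    on the analytically computed mean r^2 between loci ~100 kbp apart) so
    the realized LD hits the configured target despite the correlation
    ceilings of frequency-mismatched binary marker pairs.  Allele
    frequencies follow the configured MAF spectrum (uniform on
    [maf_min, 0.5], random allele orientation).
    """
    m = len(snp_map)
    maf = rng.uniform(config.maf_min, 0.5, size=m)
    flip = rng.random(m) < 0.5
    p = np.where(flip, 1.0 - maf, maf)
    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos"].to_numpy(dtype=float)
    t = config.target_ld_r2_at_100kbp
    if t > 0:
        lo, hi = 0.05, 1.0  # exponent multiplier (smaller = slower decay)
        for _ in range(20):
            mid = 0.5 * (lo + hi)
            slopes, marg, step_corr = _chain_slopes(p, chrom, pos, mid, t, config.ld_ref_bp)
            if _mean_r2_at_ref(step_corr, chrom, pos, config.ld_ref_bp) < t:
                hi = mid
            else:
                lo = mid
        slopes, marg, _ = _chain_slopes(p, chrom, pos, 0.5 * (lo + hi), t, config.ld_ref_bp)
    else:
        slopes = np.zeros(m)
        marg = p
    H = np.empty((n_hap, m), dtype=np.int8)
    prev_col = np.zeros(n_hap, dtype=np.int8)
    for j in range(m):
        if slopes[j] == 0.0:
            prob = np.full(n_hap, p[j])
        else:
            prob = np.clip(p[j] + slopes[j] * (prev_col - marg[j - 1]), 0.0, 1.0)
        col = (rng.random(n_hap) < prob).astype(np.int8)
        H[:, j] = col
        prev_col = col
    return H


def _recomb_prob(snp_map: pd.DataFrame) -> np.ndarray:
    """Per-gap crossover probability (Haldane, 1 cM/Mbp); 0.5 across chromosomes."""
    pos = snp_map["pos"].to_numpy(dtype=float)
    chrom = snp_map["chrom"].to_numpy()
    gaps = np.diff(pos) * 1e-8  # Morgans
    c = 0.5 * (1.0 - np.exp(-2.0 * gaps))
    c[chrom[1:] != chrom[:-1]] = 0.5
    return c


def _gametes(hapA: np.ndarray, hapB: np.ndarray, c: np.ndarray, rng) -> np.ndarray:
    """One meiosis per row of the stacked parental haplotype pair."""
    k, m = hapA.shape
    switch = np.empty((k, m), dtype=np.int8)
    switch[:, 0] = rng.integers(0, 2, size=k)
    switch[:, 1:] = rng.random((k, m - 1)) < c
    state = np.cumsum(switch, axis=1) % 2
    return np.where(state == 0, hapA, hapB).astype(np.int8)


def simulate_genotypes(
    pedigree: Pedigree, config: PopulationConfig, rng=None
) -> tuple[GenotypePanel, np.ndarray]:
    """Gene-dropped genotypes for every pedigree animal.

    Returns a GenotypePanel over all animals (subset to the genotyped ones
    for analysis) and the haplotype array (n_animals, 2, m) as ground
    truth.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    snp_map = _snp_map(config)
    m = len(snp_map)
    n = pedigree.n
    founder = pedigree.founders
    haps = np.zeros((n, 2, m), dtype=np.int8)
    fh = _founder_haplotypes(2 * int(founder.sum()), snp_map, config, rng)
    haps[founder] = fh.reshape(-1, 2, m)
    c = _recomb_prob(snp_map)

    s, d = pedigree.sire, pedigree.dam
    todo = np.nonzero(~founder)[0]
    done = founder.copy()
    while todo.size:
        ready = todo[(s[todo] < 0) | done[s[todo]]]
        ready = ready[(d[ready] < 0) | done[d[ready]]]
        # paternal gametes (unknown parent: draw a founder-spectrum haplotype)
        for which, par in ((0, s[ready]), (1, d[ready])):
            known = par >= 0
            if known.any():
                pk = par[known]
                haps[ready[known], which] = _gametes(haps[pk, 0], haps[pk, 1], c, rng)
            if (~known).any():
                haps[ready[~known], which] = _founder_haplotypes(
                    int((~known).sum()), snp_map, config, rng
                )
        done[ready] = True
        todo = np.array([i for i in todo if not done[i]], dtype=np.int64)
    panel = GenotypePanel(
        ids=list(pedigree.ids), dosages=haps.sum(axis=1).astype(float), snp_map=snp_map
    )
    return panel, haps


def panel_subset(panel: GenotypePanel, ids) -> GenotypePanel:
    """Panel restricted to the given animals (e.g. the genotyped sires)."""
    index = {a: i for i, a in enumerate(panel.ids)}
    rows = np.array([index[str(a)] for a in ids], dtype=np.int64)
    return GenotypePanel(ids=[panel.ids[i] for i in rows], dosages=panel.dosages[rows], snp_map=panel.snp_map)


# ----------------------------------------------------------------------
# breeding values and phenotypes
# ----------------------------------------------------------------------

def _gene_drop_polygenic(pedigree: Pedigree, cov: np.ndarray, rng) -> np.ndarray:
    """Breeding values by gene dropping a multivariate normal.

    Founders ~ N(0, cov); offspring = parent average + Mendelian sampling
    with variance (0.5 - 0.25 (F_s + F_d)) cov for two known parents,
    0.75 - 0.25 F_p for one, and full cov for none.
    """
    n_t = cov.shape[0]
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n_t))
    n = pedigree.n
    F = inbreeding(pedigree)
    bv = np.zeros((n, n_t))
    z = rng.standard_normal((n, n_t)) @ L.T
    s, d = pedigree.sire, pedigree.dam
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            ms = 0.5 - 0.25 * (F[si] + F[di])
            bv[i] = 0.5 * (bv[si] + bv[di]) + np.sqrt(ms) * z[i]
        elif si >= 0 or di >= 0:
            p = si if si >= 0 else di
            bv[i] = 0.5 * bv[p] + np.sqrt(0.75 - 0.25 * F[p]) * z[i]
        else:
            bv[i] = z[i]
    return bv


def _nearest_snp(snp_map: pd.DataFrame, chrom: int, pos: int) -> int:
    sel = snp_map.index[snp_map["chrom"] == chrom]
    if len(sel) == 0:
        raise ValueError(f"no SNPs on chromosome {chrom}")
    j = sel[np.argmin(np.abs(snp_map.loc[sel, "pos"].to_numpy() - pos))]
    return int(j)


def simulate_phenotypes(
    pedigree: Pedigree,
    meta: pd.DataFrame,
    config: PopulationConfig,
    rng=None,
    all_dosages: GenotypePanel | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotypes for the phenotyped animals under the analysis model.

    Each trait's breeding value is the sum of (a) optional QTL effects at
    chosen SNPs absorbing stated fractions of the genetic variance, (b) an
    optional whole-genome marker component, and (c) a gene-dropped
    polygenic remainder; marker-derived parts need ``all_dosages`` from
    :func:`simulate_genotypes`.  With ``calibrate_genetic_variance`` the
    marker parts are rescaled so their realized variance among phenotyped
    animals matches the target fraction.

    Phenotype = trait mean + contemporary-group effect + age-covariate
    effect + breeding value + residual.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    names = list(config.traits)
    n_t = len(names)
    su = np.array([config.traits[t].sigma_u2 for t in names])
    se = np.array([config.traits[t].sigma_e2 for t in names])
    gc = np.asarray(config.genetic_corr) if config.genetic_corr is not None else np.eye(n_t)
    rc = np.asarray(config.residual_corr) if config.residual_corr is not None else np.eye(n_t)

    phen_mask = meta["phenotyped"].to_numpy()
    phen_rows = pedigree.indices(meta.loc[phen_mask, "animal_id"])

    qtl_frac = sum(f for *_p, f in config.qtl_spec)
    marker_frac = config.marker_variance_fraction
    poly_frac = 1.0 - qtl_frac - marker_frac
    gcov = np.sqrt(np.outer(su, su)) * gc

    bv = np.zeros((pedigree.n, n_t))
    if poly_frac > 0:
        bv += _gene_drop_polygenic(pedigree, poly_frac * gcov, rng)

    qtls: list[dict] = []
    if qtl_frac > 0 or marker_frac > 0:
        if all_dosages is None:
            raise ValueError("marker/QTL architecture requires the gene-dropped dosages")
        order = pedigree.indices(all_dosages.ids)
        X = np.empty_like(all_dosages.dosages)
        X[order] = all_dosages.dosages  # pedigree-ordered dosages
        pfreq = X.mean(axis=0) / 2.0
        Wc = X - 2.0 * pfreq

        def calibrated(component: np.ndarray, target_var: float) -> np.ndarray:
            v = component[phen_rows].var(ddof=1)
            if config.calibrate_genetic_variance and v > 0:
                return component * np.sqrt(target_var / v)
            return component

        for chrom, pos, frac in config.qtl_spec:
            j = _nearest_snp(all_dosages.snp_map, chrom, pos)
            two_pq = max(2 * pfreq[j] * (1 - pfreq[j]), 1e-12)
            for k, t in enumerate(names):
                target = frac * su[k]
                effect = Wc[:, j] * np.sqrt(target / two_pq)
                bv[:, k] += calibrated(effect, target)
            qtls.append(
                {
                    "chrom": chrom,
                    "pos": int(all_dosages.snp_map.loc[j, "pos"]),
                    "snp_index": j,
                    "snp_id": all_dosages.snp_map.loc[j, "snp_id"],
                    "fraction": frac,
                }
            )
        if marker_frac > 0:
            beta = rng.standard_normal(Wc.shape[1])
            # scale so the linkage-equilibrium variance sum(beta^2 2pq) = 1
            beta /= np.sqrt(np.sum(beta**2 * 2 * pfreq * (1 - pfreq)))
            g = Wc @ beta
            for k, t in enumerate(names):
                target = marker_frac * su[k]
                bv[:, k] += calibrated(g * np.sqrt(target), target)

    n_phen = phen_mask.sum()
    cg = rng.integers(0, config.n_cg, size=n_phen)
    age = rng.normal(config.age_mean, config.age_sd, size=n_phen)
    rcov = np.sqrt(np.outer(se, se)) * rc
    resid = rng.standard_normal((n_phen, n_t)) @ np.linalg.cholesky(rcov + 1e-12 * np.eye(n_t)).T

    table = pd.DataFrame(
        {
            "animal_id": meta.loc[phen_mask, "animal_id"].to_numpy(),
            "cg": np.array([f"cg{c + 1:03d}" for c in cg]),
            "age": age,
        }
    )
    for k, t in enumerate(names):
        spec = config.traits[t]
        cg_eff = rng.normal(0.0, spec.cg_sd, size=config.n_cg)
        table[t] = (
            spec.mean
            + cg_eff[cg]
            + spec.age_slope * (age - config.age_mean)
            + bv[phen_rows, k]
            + resid[:, k]
        )
    truth = SimTruth(
        true_bv=pd.DataFrame(bv, index=pedigree.ids, columns=names),
        components={t: config.traits[t] for t in names},
        qtls=qtls,
    )
    return table, truth


# ----------------------------------------------------------------------
# fattening records (base-trait mode)
# ----------------------------------------------------------------------

def simulate_fattening_records(
    base: pd.DataFrame, config: PopulationConfig, rng=None
) -> pd.DataFrame:
    """Longitudinal weighing/intake records from per-animal base traits.

    Body weight grows linearly at each animal's DG around its period-mean
    BW; concentrate intake is individual while roughage intake is reported
    as the herd-unit mean (identical for all unit members), as recorded in
    the emulated design.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    days = np.array([(w - 1) * 7.0 for w in WEEK_SCHEDULE])
    mid = 0.5 * (days[0] + days[-1])
    ids = base.index.to_numpy()
    n = len(ids)
    unit = np.arange(n) // config.unit_size
    rough_i = base["DMI"].to_numpy() * base["Rrate"].to_numpy() / 100.0
    unit_mean = pd.Series(rough_i).groupby(unit).transform("mean").to_numpy()
    conc_i = base["DMI"].to_numpy() - rough_i
    rows = []
    for i, a in enumerate(ids):
        bw = base.loc[a, "BW"] + base.loc[a, "DG"] * (days - mid)
        for k, day in enumerate(days):
            rows.append(
                {
                    "animal_id": a,
                    "week": WEEK_SCHEDULE[k],
                    "day": day,
                    "body_weight": bw[k],
                    "concentrate_dmi": conc_i[i],
                    "roughage_dmi": unit_mean[i],
                    "tdn_concentrate_pct": TDN_CONCENTRATE,
                    "tdn_roughage_pct": TDN_ROUGHAGE,
                    "unit": int(unit[i]),
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# one-call population
# ----------------------------------------------------------------------

def simulate_population(config: PopulationConfig, base_trait_mode: bool = False) -> dict:
    """Generate pedigree, genotypes, phenotypes (and optionally records).

    In base-trait mode the five base traits are simulated, longitudinal
    records are built, the trait engine re-summarises them and derives the
    methane traits; otherwise the configured traits are simulated
    directly.  Returns a dict with pedigree, meta, panel (genotyped
    animals), phenotypes, truth, and records/base in base-trait mode.
    """
    rng = np.random.default_rng(config.seed)
    ped, meta = simulate_pedigree(config)
    all_panel, haps = simulate_genotypes(ped, config, rng)
    cfg = config
    if base_trait_mode:
        cfg = replace(config, traits=dict(BASE_TRAIT_DEFAULTS))
    phen, truth = simulate_phenotypes(ped, meta, cfg, rng, all_dosages=all_panel)
    truth.founder_haplotypes = haps[ped.founders]
    truth.all_dosages = all_panel
    gen_ids = meta.loc[meta["genotyped"], "animal_id"]
    out = {
        "pedigree": ped,
        "meta": meta,
        "panel": panel_subset(all_panel, gen_ids),
        "phenotypes": phen,
        "truth": truth,
        "config": cfg,
    }
    if base_trait_mode:
        base = phen.set_index("animal_id")[list(BASE_TRAIT_DEFAULTS)]
        records = simulate_fattening_records(base, cfg, rng)
        summarized = summarize_fattening(records)
        derived = predict_methane(summarized[summarized["included"]])
        table = phen[["animal_id", "cg", "age"]].set_index("animal_id")
        table = table.join(summarized[["BW", "DG", "DMI", "TDN", "Rrate"]]).join(derived)
        out["records"] = records
        out["phenotypes"] = table.reset_index()
    return out
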