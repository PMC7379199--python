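"""Readers and writers for every external format the pipeline touches.

Pedigrees and phenotypes are CSV with a header; genotypes are a dosage
table (first column the animal id, one column per SNP, NA for missing)
with a companion SNP map CSV, with the PLINK additive ``.raw`` dialect
also accepted.  Result tables are TSV.  Loading never silently drops
rows: counts are validated and failures raise with the offending row.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomic import GenotypePanel
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

PEDIGREE_COLUMNS = ["animal_id", "sire_id", "dam_id"]


def read_pedigree(path) -> Pedigree:
    """Load a pedigree CSV (animal_id, sire_id, dam_id; '0'/'' = unknown).

    Rows may be in any order; the result is sorted parents before
    offspring.  Duplicate animal ids and cycles (an animal its own
    ancestor) raise :class:`~methagen.pedigree.PedigreeError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: pedigree needs >= 3 columns")
    df = df.iloc[:, :3]
    ped = Pedigree.from_triples(df.itertuples(index=False, name=None))
    logger.info("read %d pedigree rows from %s (%d animals)", len(df), path, ped.n)
    return ped


def write_pedigree(ped: Pedigree, path) -> None:
    sire = ["0" if s < 0 else ped.ids[s] for s in ped.sire]
    dam = ["0" if d < 0 else ped.ids[d] for d in ped.dam]
    pd.DataFrame({"animal_id": ped.ids, "sire_id": sire, "dam_id": dam}).to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str, "cg": str})
    logger.info("read %d phenotype rows from %s", len(df), path)
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_genotypes(geno_path, map_path, fmt: str | None = None) -> GenotypePanel:
    """Load a dosage matrix plus SNP map, aligned by column order.

    ``fmt`` is 'csv' (default) or 'raw' (PLINK additive recode: whitespace
    separated, header FID IID PAT MAT SEX PHENOTYPE then one column per
    SNP; only IID is kept).  Missing dosages (NA) are preserved for QC.
    A row whose length disagrees with the map raises naming the row index.
    """
    geno_path = Path(geno_path)
    if fmt is None:
        fmt = "raw" if geno_path.suffix == ".raw" else "csv"
    snp_map = pd.read_csv(map_path)
    m = len(snp_map)
    lead = 6 if fmt == "raw" else 1
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(geno_path) as fh:
        header = fh.readline()
        tokens = header.split() if fmt == "raw" else header.rstrip("\n").split(",")
        if len(tokens) - lead != m:
            raise ValueError(f"{geno_path}: {len(tokens) - lead} SNP columns but map has {m} rows")
        id_col = tokens.index("IID") if fmt == "raw" else 0
        for i, line in enumerate(fh):
            parts = line.split() if fmt == "raw" else line.rstrip("\n").split(",")
            if len(parts) - lead != m:
                raise ValueError(
                    f"{geno_path}: row {i} has {len(parts) - lead} dosages, map has {m}"
                )
            ids.append(parts[id_col])
            row = np.array(
                [np.nan if tok in ("NA", "", "nan") else float(tok) for tok in parts[lead:]]
            )
            rows.append(row)
    dos = np.vstack(rows) if rows else np.empty((0, m))
    bad = np.isfinite(dos) & ~np.isin(dos, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"{geno_path}: invalid dosage {dos[i, j]} at row {i}, SNP {j}")
    panel = GenotypePanel(ids=ids, dosages=dos, snp_map=snp_map)
    logger.info("read %d animals x %d SNPs from %s", panel.n_animals, panel.n_snps, geno_path)
    return panel


def write_genotypes(panel: GenotypePanel, geno_path, map_path) -> None:
    body = pd.DataFrame(panel.dosages, columns=panel.snp_map["snp_id"])
    body = body.map(lambda v: "NA" if not np.isfinite(v) else str(int(v)) if v == int(v) else str(v))
    body.insert(0, "animal_id", panel.ids)
    body.to_csv(geno_path, index=False)
    panel.snp_map.to_csv(map_path, index=False)


SNP_TABLE_COLUMNS = ["chrom", "pos", "snp_id", "beta", "sd_beta", "pvalue", "weight"]
WINDOW_COLUMNS = ["chrom", "start_bp", "end_bp", "n_snps", "variance_pct"]
REGION_COLUMNS = ["chrom", "start_bp", "end_bp", "n_snps", "max_variance_pct"]


def write_ssgwas_tables(result, out_dir) -> dict[str, Path]:
    """Write per-SNP, per-window and QTL-region TSVs with fixed columns."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "snp": out / "snp_effects.tsv",
        "window": out / "windows.tsv",
        "region": out / "regions.tsv",
    }
    result.snp_table.reindex(columns=SNP_TABLE_COLUMNS).to_csv(paths["snp"], sep="\t", index=False)
    result.windows.reindex(columns=WINDOW_COLUMNS).to_csv(paths["window"], sep="\t", index=False)
    result.regions.reindex(columns=REGION_COLUMNS).to_csv(paths["region"], sep="\t", index=False)
    return paths


DEFAULT_CONFIG = {
    "seed": 2020,
    "qc": {"maf_min": 0.01, "call_rate_min": 0.95, "hwe_p_min": 0.001},
    "ssgwas": {
        "alpha_blend": 0.05,
        "n_weight_iters": 2,
        "window_bp": 100_000,
        "threshold_pct": 5.0,
        "bonferroni_alpha": 0.05,
    },
    "model": {"trait": "CH4", "cg_col": "cg", "age_col": "age", "kinship": "A"},
    "simulate": {},
}


def load_config(path=None) -> dict:
    """Merge a YAML config over the defaults and log the resolved values."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    logger.info("resolved config: %s", cfg)
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
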