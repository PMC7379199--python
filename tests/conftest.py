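import numpy as np
import pytest

import methagen as mg


@pytest.fixture(scope="session")
def trio():
    """Smallest family: offspring of two founders."""
    return mg.Pedigree.from_triples([("o", "s", "d"), ("s", "0", "0"), ("d", "0", "0")])


@pytest.fixture(scope="session")
def random_pedigree():
    """500-animal random-mating pedigree with overlapping generations."""
    rng = np.random.default_rng(11)
    triples = [(f"F{i}", "0", "0") for i in range(40)]
    ids = [t[0] for t in triples]
    for i in range(460):
        s, d = rng.choice(len(ids), size=2, replace=False)
        triples.append((f"A{i}", ids[s], ids[d]))
        ids.append(f"A{i}")
    return mg.Pedigree.from_triples(triples)


@pytest.fixture(scope="session")
def small_population():
    """Compact sire-progeny population with genotypes and one trait."""
    cfg = mg.PopulationConfig(
        n_sires=40,
        progeny_per_sire=8,
        n_cg=8,
        n_chromosomes=2,
        n_snps_per_chrom=120,
        chrom_length_bp=30_000_000,
        traits={"CH4": mg.TraitSpec(251.3, 148.3, 102.8, cg_sd=15.0, age_slope=0.05)},
        seed=90,
    )
    return mg.simulate_population(cfg)
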