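import numpy as np
import pytest

from polydiff.data_model import AlleleSet, LocusInfo, MicrosatDataset, PopulationInfo
from polydiff.simulate import (
    GenoSimConfig,
    PhenoSimConfig,
    TraitSim,
    simulate_genotypes,
    simulate_phenotypes,
)


def make_dataset(rows, loci=None, populations=None):
    """Build a MicrosatDataset from {individual: (pop, {locus: sizes})}."""
    if loci is None:
        locus_names = sorted({loc for _, (_, g) in rows.items() for loc in g})
        loci = [LocusInfo(name, 2) for name in locus_names]
    genotypes = {
        ind: {loc.name: AlleleSet(frozenset(geno.get(loc.name, ()))) for loc in loci}
        for ind, (_, geno) in rows.items()
    }
    pop_of = {ind: pop for ind, (pop, _) in rows.items()}
    return MicrosatDataset(loci, genotypes, pop_of, populations or [])


@pytest.fixture
def two_pop_dataset():
    """Two populations x three individuals x two dinucleotide loci."""
    return make_dataset(
        {
            "a1": ("A", {"L1": {100, 102}, "L2": {200}}),
            "a2": ("A", {"L1": {100}, "L2": {200, 204}}),
            "a3": ("A", {"L1": {102}, "L2": {200}}),
            "b1": ("B", {"L1": {110, 112}, "L2": {220}}),
            "b2": ("B", {"L1": {110}, "L2": {220, 222}}),
            "b3": ("B", {"L1": {112}, "L2": {222}}),
        }
    )


@pytest.fixture
def sim_dataset():
    cfg = GenoSimConfig(
        n_populations=4,
        n_individuals=8,
        n_loci=3,
        group_of_population=("KE", "KE", "QE", "QN"),
        seed=11,
    )
    return simulate_genotypes(cfg)


@pytest.fixture
def pheno_records():
    cfg = PhenoSimConfig(
        traits={
            "leaf_length": TraitSim(36.0, v_population=38.83, v_plant=27.55),
            "plant_height": TraitSim(190.0, v_region=10.0, v_population=730.06,
                                     v_plant=1227.30),
        },
        n_regions=2,
        populations_per_region=4,
        plants_per_population=10,
        seed=7,
    )
    return simulate_phenotypes(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
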