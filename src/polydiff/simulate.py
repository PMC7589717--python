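"""Synthetic genotype, phenotype and coordinate generators.

The generators reproduce the statistical structure the downstream analyses
assume, so every pipeline stage can be exercised without field data:

* genotypes: stepwise-mutation-like allele sizes on the repeat-unit lattice,
  with a latent per-population mean per locus (between-population spread)
  and per-individual draws around it (within-population spread).  Each
  individual carries 1..k distinct alleles where k is the ploidy cap of its
  group, emulating dosage-ambiguous polyploid fragment data.
* phenotypes: the nested random-effects model
  ``Y = mu + region + population(region) + haplotype(population) + plant``
  with independent zero-mean normal effects of configured variances.
* coordinates: uniform sites in a bounding box of a given extent.

All outputs are deterministic functions of the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from polydiff.data_model import (
    AlleleSet,
    LocusInfo,
    MicrosatDataset,
    PhenotypeRecord,
    PopulationInfo,
)

#: The nine PaGT dinucleotide loci with their published fragment-size ranges.
DEFAULT_LOCI = (
    LocusInfo("PaGT4", 2, (285, 297)),
    LocusInfo("PaGT14", 2, (191, 209)),
    LocusInfo("PaGT8", 2, (192, 196)),
    LocusInfo("PaGT13", 2, (225, 237)),
    LocusInfo("PaGT9", 2, (209, 247)),
    LocusInfo("PaGT11", 2, (160, 166)),
    LocusInfo("PaGT22", 2, (190, 226)),
    LocusInfo("PaGT12", 2, (183, 190)),
    LocusInfo("PaGT16", 2, (248, 325)),
)

#: Ploidy caps (max distinct alleles) by sampling group.
DEFAULT_PLOIDY = {"KE": 6, "QE": 4, "QN": 2}

#: Group of each of the 20 default populations (9 Kashmir invasive,
#: 10 Quebec invasive, 1 Quebec native).
DEFAULT_GROUPS = ("KE",) * 9 + ("QE",) * 10 + ("QN",)


@dataclass(frozen=True)
class GenoSimConfig:
    """Study conditions for the genotype generator.

    ``between_pop_sd`` / ``within_pop_sd`` are in repeat units; their squared
    ratio sets the expected allele-size variance partition, hence R_ST ~
    between^2 / (between^2 + within^2).  The defaults (0.75, 1.0) put the
    simulated populations in the strong-differentiation regime (R_ST ~ 0.35)
    with a handful of distinct alleles per population and locus, the scale
    reported for structured reed populations.
    """

    n_populations: int = 20
    n_individuals: int = 25
    n_loci: int = 9
    ploidy_by_group: dict = field(default_factory=lambda: dict(DEFAULT_PLOIDY))
    group_of_population: tuple = DEFAULT_GROUPS
    repeat_unit: int = 2
    between_pop_sd: float = 0.75
    within_pop_sd: float = 1.0
    jitter_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_populations, self.n_individuals, self.n_loci) < 1:
            raise ValueError("counts must be >= 1")
        if self.between_pop_sd < 0 or self.within_pop_sd < 0:
            raise ValueError("sds must be >= 0")
        if self.jitter_rate < 0 or self.jitter_rate > 1:
            raise ValueError("jitter_rate must lie in [0, 1]")
        groups = self.group_of_population
        if len(groups) < self.n_populations:
            # cycle the group labels if fewer than populations
            reps = -(-self.n_populations // len(groups))
            object.__setattr__(self, "group_of_population", (groups * reps)[: self.n_populations])
        else:
            object.__setattr__(self, "group_of_population", tuple(groups[: self.n_populations]))
        for g in self.group_of_population:
            if g not in self.ploidy_by_group:
                raise ValueError(f"group {g!r} has no ploidy cap")


def simulate_genotypes(config: GenoSimConfig) -> MicrosatDataset:
    """Draw a dosage-ambiguous microsatellite dataset.

    Per locus, each population gets a latent mean allele size on the repeat
    lattice (sd ``between_pop_sd``); each individual draws k distinct allele
    sizes around that mean (sd ``within_pop_sd``, rounded to the lattice),
    k uniform on 1..ploidy cap.  With ``jitter_rate`` an allele slips one
    extra lattice step.
    """
    rng = np.random.default_rng(config.seed)
    unit = config.repeat_unit
    if config.n_loci <= len(DEFAULT_LOCI):
        loci = [replace(l, repeat_unit=unit) for l in DEFAULT_LOCI[: config.n_loci]]
    else:
        loci = [replace(l, repeat_unit=unit) for l in DEFAULT_LOCI] + [
            LocusInfo(f"SIM{i}", unit, (150 + 40 * i, 190 + 40 * i))
            for i in range(config.n_loci - len(DEFAULT_LOCI))
        ]

    group_counts: dict[str, int] = {}
    pop_ids, pop_groups = [], []
    for g in config.group_of_population:
        group_counts[g] = group_counts.get(g, 0) + 1
        pop_ids.append(f"{g}{group_counts[g]}")
        pop_groups.append(g)
    populations = [
        PopulationInfo(pid, region="Kashmir" if g == "KE" else "Quebec",
                       status="native" if g == "QN" else "invasive")
        for pid, g in zip(pop_ids, pop_groups)
    ]

    centers = {
        loc.name: (loc.size_range[0] + loc.size_range[1]) // 2 if loc.size_range else 200
        for loc in loci
    }
    # latent population means, in repeat-lattice steps relative to the center
    pop_mean_steps = {
        (pid, loc.name): int(np.rint(rng.normal(0.0, config.between_pop_sd)))
        for pid in pop_ids
        for loc in loci
    }

    genotypes: dict[str, dict[str, AlleleSet]] = {}
    pop_of: dict[str, str] = {}
    for pid, group in zip(pop_ids, pop_groups):
        cap = config.ploidy_by_group[group]
        for j in range(config.n_individuals):
            ind = f"{pid}-{j + 1:02d}"
            row: dict[str, AlleleSet] = {}
            for loc in loci:
                k = int(rng.integers(1, cap + 1))
                steps = pop_mean_steps[(pid, loc.name)] + np.rint(
                    rng.normal(0.0, config.within_pop_sd, size=k)
                ).astype(int)
                if config.jitter_rate > 0:
                    slips = rng.random(k) < config.jitter_rate
                    steps = steps + slips * rng.choice([-1, 1], size=k)
                sizes = centers[loc.name] + unit * steps
                sizes = sizes[sizes > 0]
                row[loc.name] = AlleleSet(frozenset(int(s) for s in sizes))
            genotypes[ind] = row
            pop_of[ind] = pid
    return MicrosatDataset(loci, genotypes, pop_of, populations)


@dataclass(frozen=True)
class TraitSim:
    """Grand mean and variance components for one simulated trait."""

    mean: float
    v_region: float = 0.0
    v_population: float = 0.0
    v_haplotype: float = 0.0
    v_plant: float = 0.0
    v_residual: float = 0.0

    def __post_init__(self) -> None:
        for name in ("v_region", "v_population", "v_haplotype", "v_plant", "v_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Default trait parameters: published variance decomposition of the seven
#: morphometric traits, grand means near the observed population means.
DEFAULT_TRAIT_SIMS = {
    "plant_height": TraitSim(190.0, 0.0, 730.06, 20.76, 1227.30, 1.0096),
    "stem_diameter": TraitSim(6.2, 0.965, 0.371, 0.0, 0.555, 1.123),
    "fresh_mass": TraitSim(4.7, 0.366, 2.160, 0.140, 7.846, 0.932),
    "dry_mass": TraitSim(2.4, 0.37, 0.577, 0.051, 1.743, 0.879),
    "leaf_length": TraitSim(36.0, 31.5, 38.83, 0.0142, 27.55, 1.155),
    "internode_length": TraitSim(13.6, 0.0, 6.07, 0.0, 6.08, 0.884),
    "leaf_width": TraitSim(1.78, 0.69, 0.0298, 0.0233, 0.0, 0.1144),
}


@dataclass(frozen=True)
class PhenoSimConfig:
    """Nested sampling design plus per-trait means and variance components."""

    traits: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_SIMS))
    n_regions: int = 2
    populations_per_region: int = 8
    plants_per_population: int = 25
    replicates: int = 1
    haplotypes_per_population: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_regions, self.populations_per_region,
               self.plants_per_population, self.replicates,
               self.haplotypes_per_population) < 1:
            raise ValueError("design counts must be >= 1")


def simulate_phenotypes(config: PhenoSimConfig) -> list[PhenotypeRecord]:
    """Draw trait measurements from the nested random-effects model.

    One record is emitted per replicate measurement (``replicates`` rows per
    plant), so the residual variance stays separable from the plant effect
    whenever replicates > 1.  Values are floored at 0 (traits are physical
    measurements).
    """
    rng = np.random.default_rng(config.seed)
    records: list[PhenotypeRecord] = []
    n_r, n_p = config.n_regions, config.populations_per_region
    n_h, n_pl, n_rep = config.haplotypes_per_population, config.plants_per_population, config.replicates

    effects: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for tname, ts in config.traits.items():
        effects[tname] = {
            "region": rng.normal(0, math.sqrt(ts.v_region), n_r),
            "population": rng.normal(0, math.sqrt(ts.v_population), (n_r, n_p)),
            "haplotype": rng.normal(0, math.sqrt(ts.v_haplotype), (n_r, n_p, n_h)),
            "plant": rng.normal(0, math.sqrt(ts.v_plant), (n_r, n_p, n_h, n_pl)),
            "resid": rng.normal(0, math.sqrt(ts.v_residual), (n_r, n_p, n_h, n_pl, n_rep)),
        }

    for i in range(n_r):
        region = f"R{i + 1}"
        for j in range(n_p):
            pop = f"{region}P{j + 1}"
            for k in range(n_h):
                haplo = f"{pop}H{k + 1}"
                for l in range(n_pl):
                    plant = f"{pop}H{k + 1}-{l + 1:03d}"
                    for r in range(n_rep):
                        traits = {}
                        for tname, ts in config.traits.items():
                            eff = effects[tname]
                            value = (
                                ts.mean
                                + eff["region"][i]
                                + eff["population"][i, j]
                                + eff["haplotype"][i, j, k]
                                + eff["plant"][i, j, k, l]
                                + eff["resid"][i, j, k, l, r]
                            )
                            traits[tname] = max(0.0, float(value))
                        records.append(
                            PhenotypeRecord(region, pop, haplo, plant, traits,
                                            replicate=str(r + 1))
                        )
    return records


def simulate_coordinates(
    n: int, extent_km: float, seed: int = 0, origin: tuple[float, float] = (45.0, -72.0)
) -> list[PopulationInfo]:
    """Scatter ``n`` sites uniformly in an ``extent_km`` x ``extent_km`` box."""
    if n < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(seed)
    lat0, lon0 = origin
    km_per_deg_lat = 111.19
    km_per_deg_lon = km_per_deg_lat * math.cos(math.radians(lat0))
    lats = lat0 + rng.random(n) * extent_km / km_per_deg_lat
    lons = lon0 + rng.random(n) * extent_km / km_per_deg_lon
    return [
        PopulationInfo(f"P{i + 1:02d}", region="sim", status="sim",
                       latitude=float(lats[i]), longitude=float(lons[i]))
        for i in range(n)
    ]
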