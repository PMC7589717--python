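"""Domain types and delimited-text readers/writers.

Genotypes are dosage-ambiguous: each individual carries a *set* of distinct
microsatellite fragment sizes per locus (1 up to the ploidy cap), with the
copy number of each allele unobserved.  Phenotypes follow the nested
region > population > haplotype > plant sampling design.

File dialects
-------------
* Genotypes: wide CSV, one row per individual.  Columns ``individual``,
  ``population`` then, for each locus, ``<locus>.1`` ... ``<locus>.k``
  (k = maximum ploidy); blank cells mean "no further alleles" and a fully
  blank locus means missing.  Locus metadata (repeat unit, size range) is
  carried in ``#locus`` comment lines before the header.
* Phenotypes: CSV with ``region,population,haplotype,plant`` plus one column
  per trait.
* Populations/coordinates: CSV ``id,region,status,latitude,longitude,
  elevation``; latitude/longitude accept decimal degrees or DMS strings.
* Distance matrices: labeled square CSV, or PHYLIP square format.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical trait column order (units: cm, mm, g, g, cm, cm, cm)
TRAITS = (
    "plant_height",
    "stem_diameter",
    "fresh_mass",
    "dry_mass",
    "internode_length",
    "leaf_length",
    "leaf_width",
)

#: factor columns of a phenotype table (everything else is a trait)
FACTOR_COLUMNS = ("region", "population", "haplotype", "plant", "replicate")

MAX_PLOIDY = 8


class ParseError(ValueError):
    """Malformed input file content."""


@dataclass(frozen=True)
class LocusInfo:
    """A microsatellite locus: name, repeat motif length, optional bp range."""

    name: str
    repeat_unit: int = 2
    size_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.repeat_unit < 1:
            raise ValueError(f"repeat_unit must be >= 1, got {self.repeat_unit}")
        if self.size_range is not None and self.size_range[0] > self.size_range[1]:
            raise ValueError(f"size_range min > max: {self.size_range}")


@dataclass(frozen=True)
class AlleleSet:
    """Distinct fragment sizes (bp) observed for one individual at one locus.

    An empty set marks a missing genotype.  Dosage is unobserved, so the
    representation is a set, never a multiset.
    """

    sizes: frozenset = frozenset()

    def __post_init__(self) -> None:
        sizes = frozenset(int(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if sizes:
            if len(sizes) > MAX_PLOIDY:
                raise ValueError(f"more than {MAX_PLOIDY} alleles: {sorted(sizes)}")
            if any(s <= 0 for s in sizes):
                raise ValueError(f"allele sizes must be positive: {sorted(sizes)}")

    @property
    def missing(self) -> bool:
        return not self.sizes

    def sorted(self) -> list[int]:
        return sorted(self.sizes)

    def __len__(self) -> int:
        return len(self.sizes)

    def __iter__(self):
        return iter(sorted(self.sizes))


MISSING = AlleleSet()


@dataclass(frozen=True)
class PopulationInfo:
    """Sampling site metadata; coordinates in decimal degrees."""

    id: str
    region: str = ""
    status: str = ""
    latitude: float = float("nan")
    longitude: float = float("nan")
    elevation: float = float("nan")

    def __post_init__(self) -> None:
        if not math.isnan(self.latitude) and abs(self.latitude) > 90:
            raise ValueError(f"|latitude| > 90: {self.latitude}")
        if not math.isnan(self.longitude) and abs(self.longitude) > 180:
            raise ValueError(f"|longitude| > 180: {self.longitude}")


@dataclass
class MicrosatDataset:
    """Individuals x loci table of ambiguous-dosage allele sets.

    Parameters
    ----------
    loci : ordered list of LocusInfo
    genotypes : mapping individual id -> {locus name -> AlleleSet}
    population_of : mapping individual id -> population id
    populations : optional PopulationInfo list (site metadata)
    """

    loci: list[LocusInfo]
    genotypes: dict[str, dict[str, AlleleSet]]
    population_of: dict[str, str]
    populations: list[PopulationInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        locus_names = {loc.name for loc in self.loci}
        if len(locus_names) != len(self.loci):
            raise ValueError("duplicate locus names")
        known_pops = {p.id for p in self.populations}
        for ind, row in self.genotypes.items():
            if ind not in self.population_of:
                raise ValueError(f"individual {ind!r} has no population")
            if known_pops and self.population_of[ind] not in known_pops:
                raise ValueError(
                    f"individual {ind!r} assigned to unknown population "
                    f"{self.population_of[ind]!r}"
                )
            if set(row) != locus_names:
                raise ValueError(f"individual {ind!r} missing locus columns")

    @property
    def individuals(self) -> list[str]:
        return list(self.genotypes)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    @property
    def population_ids(self) -> list[str]:
        if self.populations:
            return [p.id for p in self.populations]
        seen: dict[str, None] = {}
        for ind in self.genotypes:
            seen.setdefault(self.population_of[ind], None)
        return list(seen)

    def locus(self, name: str) -> LocusInfo:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)

    def members(self, population: str) -> list[str]:
        return [i for i in self.genotypes if self.population_of[i] == population]

    def max_alleles(self, individuals: Iterable[str] | None = None) -> int:
        inds = list(individuals) if individuals is not None else self.individuals
        best = 0
        for ind in inds:
            for aset in self.genotypes[ind].values():
                best = max(best, len(aset))
        return best

    def subset(self, populations: Sequence[str]) -> "MicrosatDataset":
        keep = set(populations)
        geno = {
            i: row for i, row in self.genotypes.items() if self.population_of[i] in keep
        }
        pops = [p for p in self.populations if p.id in keep]
        pop_of = {i: self.population_of[i] for i in geno}
        return MicrosatDataset(self.loci, geno, pop_of, pops)


@dataclass(frozen=True)
class PhenotypeRecord:
    """One measurement of a plant under the nested sampling design.

    ``replicate`` distinguishes repeated measurements of the same plant
    (some traits are measured several times per individual); single-
    measurement designs leave it at "1".
    """

    region: str
    population: str
    haplotype: str
    plant: str
    traits: Mapping[str, float]
    replicate: str = "1"

    def __post_init__(self) -> None:
        for label in (self.region, self.population, self.haplotype, self.plant,
                      self.replicate):
            if not str(label):
                raise ValueError("nesting labels must be non-empty")
        for name, value in self.traits.items():
            if value is not None and not math.isnan(value) and value < 0:
                raise ValueError(f"negative trait value {name}={value}")


def records_to_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    """Tabulate phenotype records (factors first, then trait columns)."""
    trait_names: dict[str, None] = {}
    for rec in records:
        for t in rec.traits:
            trait_names.setdefault(t, None)
    rows = []
    for rec in records:
        row = {
            "region": rec.region,
            "population": rec.population,
            "haplotype": rec.haplotype,
            "plant": rec.plant,
            "replicate": rec.replicate,
        }
        for t in trait_names:
            row[t] = rec.traits.get(t, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def plant_level(frame: pd.DataFrame) -> pd.DataFrame:
    """Average replicate measurements: one row per plant."""
    factors = ["region", "population", "haplotype", "plant"]
    traits = [c for c in frame.columns if c not in FACTOR_COLUMNS]
    return frame.groupby(factors, sort=False, as_index=False)[traits].mean()


def frame_to_records(frame: pd.DataFrame) -> list[PhenotypeRecord]:
    trait_cols = [c for c in frame.columns if c not in FACTOR_COLUMNS]
    records = []
    for _, row in frame.iterrows():
        records.append(
            PhenotypeRecord(
                region=str(row["region"]),
                population=str(row["population"]),
                haplotype=str(row["haplotype"]),
                plant=str(row["plant"]),
                replicate=str(row["replicate"]) if "replicate" in frame.columns else "1",
                traits={t: float(row[t]) for t in trait_cols},
            )
        )
    return records


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal is not zero")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < -1e-12):
                raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major order (scipy convention)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="label")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        labels = [str(l) for l in frame.index]
        if [str(c) for c in frame.columns] != labels:
            raise ParseError(f"{path}: row and column labels differ")
        return cls(labels, frame.to_numpy(dtype=float))

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                name = label[:10].ljust(10)
                fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            lines = [l.rstrip("\n") for l in fh if l.strip()]
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for line in lines[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(labels, np.array(rows))


# ---------------------------------------------------------------------------
# coordinate parsing

_DMS_RE = re.compile(
    r"""^\s*
    (?P<pre>[NSEW])?\s*
    (?P<deg>\d+(?:\.\d+)?)\s*[°d]\s*
    (?:(?P<min>\d+(?:\.\d+)?)\s*[′'’m]\s*)?
    (?:(?P<sec>\d+(?:\.\d+)?)\s*[″"”s]\s*)?
    (?P<post>[NSEW])?\s*$""",
    re.VERBOSE,
)


def parse_dms(text: str) -> float:
    """Parse a degrees-minutes-seconds coordinate to decimal degrees.

    The hemisphere letter may precede or follow the numbers; W and S are
    negative.  Examples: ``"34°5′19″ N"`` -> 34.0886, ``"W 70°5′41″"`` ->
    -70.0947.
    """
    m = _DMS_RE.match(text)
    if m is None:
        raise ParseError(f"cannot parse coordinate {text!r}")
    hemis = [h for h in (m.group("pre"), m.group("post")) if h]
    if len(hemis) != 1:
        raise ParseError(f"coordinate needs exactly one hemisphere letter: {text!r}")
    deg = float(m.group("deg"))
    minutes = float(m.group("min") or 0.0)
    seconds = float(m.group("sec") or 0.0)
    if minutes >= 60 or seconds >= 60:
        raise ParseError(f"minutes/seconds out of range in {text!r}")
    value = deg + minutes / 60.0 + seconds / 3600.0
    if hemis[0] in "SW":
        value = -value
    if hemis[0] in "NS" and value < -90 or hemis[0] in "NS" and value > 90:
        raise ParseError(f"latitude out of range: {text!r}")
    return value


def _parse_coordinate(raw: str) -> float:
    raw = str(raw).strip()
    try:
        return float(raw)
    except ValueError:
        return parse_dms(raw)


# ---------------------------------------------------------------------------
# genotype tables


def write_genotypes(dataset: MicrosatDataset, path: str | Path) -> None:
    """Write the wide genotype CSV (with ``#locus`` metadata lines)."""
    width = {
        loc.name: max(1, max((len(dataset.genotypes[i][loc.name]) for i in dataset.genotypes), default=1))
        for loc in dataset.loci
    }
    with open(path, "w") as fh:
        for loc in dataset.loci:
            rng = (
                f",{loc.size_range[0]},{loc.size_range[1]}" if loc.size_range else ",,"
            )
            fh.write(f"#locus,{loc.name},{loc.repeat_unit}{rng}\n")
        header = ["individual", "population"]
        for loc in dataset.loci:
            header += [f"{loc.name}.{k + 1}" for k in range(width[loc.name])]
        fh.write(",".join(header) + "\n")
        for ind, row in dataset.genotypes.items():
            cells = [ind, dataset.population_of[ind]]
            for loc in dataset.loci:
                sizes = row[loc.name].sorted()
                sizes += [""] * (width[loc.name] - len(sizes))
                cells += [str(s) for s in sizes]
            fh.write(",".join(cells) + "\n")


def read_genotypes(
    path: str | Path,
    loci_spec: Sequence[LocusInfo] | None = None,
    populations: Sequence[PopulationInfo] | None = None,
) -> MicrosatDataset:
    """Read the wide genotype CSV written by :func:`write_genotypes`.

    ``loci_spec`` overrides the ``#locus`` metadata lines; ``populations``
    enables rejection of unknown population ids.
    """
    meta: dict[str, LocusInfo] = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#locus,"):
                parts = line.split(",")
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: malformed #locus line")
                name, unit = parts[1], int(parts[2])
                size_range = None
                if len(parts) >= 5 and parts[3] and parts[4]:
                    size_range = (int(parts[3]), int(parts[4]))
                meta[name] = LocusInfo(name, unit, size_range)
                continue
            if line.startswith("#"):
                continue
            cells = [c.strip() for c in line.split(",")]
            if header is None:
                header = cells
            else:
                rows.append((lineno, cells))
    if header is None or header[:2] != ["individual", "population"]:
        raise ParseError(f"{path}: missing 'individual,population,...' header")

    locus_cols: dict[str, list[int]] = {}
    for idx, col in enumerate(header[2:], start=2):
        name = col.rsplit(".", 1)[0]
        locus_cols.setdefault(name, []).append(idx)
    if loci_spec is not None:
        loci = list(loci_spec)
        if {l.name for l in loci} != set(locus_cols):
            raise ParseError(f"{path}: loci_spec does not match file columns")
    else:
        loci = [meta.get(name, LocusInfo(name)) for name in locus_cols]

    genotypes: dict[str, dict[str, AlleleSet]] = {}
    pop_of: dict[str, str] = {}
    for lineno, cells in rows:
        if len(cells) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(cells)}"
            )
        ind, pop = cells[0], cells[1]
        if ind in genotypes:
            raise ParseError(f"{path}:{lineno}: duplicate individual {ind!r}")
        row: dict[str, AlleleSet] = {}
        for name, cols in locus_cols.items():
            sizes = []
            for c in cols:
                if cells[c]:
                    try:
                        sizes.append(int(cells[c]))
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}:{lineno}: non-integer allele size {cells[c]!r}"
                        ) from exc
            row[name] = AlleleSet(frozenset(sizes))
        genotypes[ind] = row
        pop_of[ind] = pop
    return MicrosatDataset(
        loci, genotypes, pop_of, list(populations) if populations else []
    )


# ---------------------------------------------------------------------------
# phenotype tables


def write_phenotypes(records: Sequence[PhenotypeRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read the phenotype CSV; rejects negative values and duplicate keys."""
    frame = pd.read_csv(path, dtype={c: str for c in FACTOR_COLUMNS})
    required = {"region", "population", "haplotype", "plant"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: missing factor columns {sorted(required - set(frame.columns))}")
    key = ["population", "plant"] + (["replicate"] if "replicate" in frame.columns else [])
    dup = frame.duplicated(subset=key)
    if dup.any():
        first = frame.loc[dup, key].iloc[0]
        raise ParseError(
            f"{path}: duplicated {tuple(key)} key {tuple(first)}"
        )
    trait_cols = [c for c in frame.columns if c not in FACTOR_COLUMNS]
    for col in trait_cols:
        values = pd.to_numeric(frame[col], errors="coerce")
        if ((values < 0) & values.notna()).any():
            raise ParseError(f"{path}: negative value in trait column {col!r}")
        frame[col] = values
    return frame_to_records(frame)


# ---------------------------------------------------------------------------
# population / coordinate tables


def write_populations(populations: Sequence[PopulationInfo], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": p.id,
                "region": p.region,
                "status": p.status,
                "latitude": p.latitude,
                "longitude": p.longitude,
                "elevation": p.elevation,
            }
            for p in populations
        ]
    ).to_csv(path, index=False)


def read_populations(path: str | Path) -> list[PopulationInfo]:
    frame = pd.read_csv(path, dtype=str).fillna("")
    pops = []
    for _, row in frame.iterrows():
        pops.append(
            PopulationInfo(
                id=str(row["id"]),
                region=str(row.get("region", "")),
                status=str(row.get("status", "")),
                latitude=_parse_coordinate(row["latitude"]) if row.get("latitude") else float("nan"),
                longitude=_parse_coordinate(row["longitude"]) if row.get("longitude") else float("nan"),
                elevation=float(row["elevation"]) if row.get("elevation") else float("nan"),
            )
        )
    return pops
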