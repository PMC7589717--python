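"""Per-population diversity statistics for dosage-ambiguous genotypes.

All frequency-based statistics use presence weighting: each distinct allele
in an individual's set contributes one observation, since allele copy
number is unobservable in polyploid fragment data.  "Heterozygosity" is
therefore phenotypic: H_O is the fraction of individuals showing >= 2
distinct alleles at a locus, H_E the gene-diversity analogue 1 - sum(p^2).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from polydiff.data_model import MicrosatDataset


@dataclass
class DiversitySummary:
    """Per-population diversity table plus overall means.

    ``per_population`` columns: n, P, A, A_p, A_R, H_O, H_E.  ``overall``
    adds ``A_pooled``: the mean number of distinct alleles per locus pooled
    over all populations (a dataset-level count, reported separately because
    it is not comparable with the per-population means).
    """

    per_population: pd.DataFrame
    overall: pd.Series
    rarefaction_g: int


def allele_frequencies(
    dataset: MicrosatDataset, scope: str = "all"
) -> dict:
    """Presence-weighted allele frequencies per locus.

    scope="all" returns ``{locus: {allele: freq}}`` over the whole dataset;
    scope="population" returns ``{population: {locus: {allele: freq}}}``.
    Loci with no data are flagged with an empty dict.
    """
    if scope == "all":
        return {
            loc: _locus_freqs(dataset, loc, dataset.individuals)
            for loc in dataset.locus_names
        }
    if scope == "population":
        return {
            pop: {
                loc: _locus_freqs(dataset, loc, dataset.members(pop))
                for loc in dataset.locus_names
            }
            for pop in dataset.population_ids
        }
    raise ValueError(f"unknown scope {scope!r}")


def _locus_counts(dataset: MicrosatDataset, locus: str, individuals) -> Counter:
    counts: Counter = Counter()
    for ind in individuals:
        for allele in dataset.genotypes[ind][locus].sizes:
            counts[allele] += 1
    return counts


def _locus_freqs(dataset: MicrosatDataset, locus: str, individuals) -> dict:
    counts = _locus_counts(dataset, locus, individuals)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {a: c / total for a, c in sorted(counts.items())}


def pic(frequencies) -> float:
    """Polymorphism information content, 1 - sum(p_i^2)."""
    freqs = np.asarray(
        list(frequencies.values()) if isinstance(frequencies, dict) else frequencies,
        dtype=float,
    )
    if freqs.size == 0:
        raise ValueError("no allele frequencies")
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError(f"frequencies sum to {freqs.sum()}, not 1")
    return float(1.0 - np.sum(freqs**2))


def _rarefied_richness(counts: Counter, g: int) -> float:
    """Expected number of distinct alleles in a hypergeometric subsample of g
    allele observations."""
    n = sum(counts.values())
    if g > n:
        raise ValueError(f"rarefaction size {g} exceeds sample {n}")
    # E[A_R] = sum_a 1 - C(n - n_a, g)/C(n, g), in log space for stability
    def log_comb(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    total = 0.0
    for c in counts.values():
        if n - c < g:
            total += 1.0
        else:
            total += 1.0 - np.exp(log_comb(n - c, g) - log_comb(n, g))
    return float(total)


def diversity_summary(
    dataset: MicrosatDataset, rarefaction_g: int | None = None
) -> DiversitySummary:
    """Per-population P, A, A_p, A_R, H_O, H_E and their overall means.

    P = % of scored loci with >= 2 distinct alleles in the population;
    A (A_p) = mean distinct alleles over all (polymorphic) scored loci;
    A_R = rarefied allelic richness at ``rarefaction_g`` allele observations
    (default: the smallest population x locus observation count);
    H_O = fraction of individuals with >= 2 alleles, averaged over loci;
    H_E = 1 - sum(p^2) averaged over loci.
    """
    pops = dataset.population_ids
    loci = dataset.locus_names

    obs_counts = []
    for pop in pops:
        members = dataset.members(pop)
        if len(members) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        for loc in loci:
            n_obs = sum(len(dataset.genotypes[i][loc]) for i in members)
            if n_obs > 0:
                obs_counts.append(n_obs)
    if not obs_counts:
        raise ValueError("dataset has no scored genotypes")
    g = min(obs_counts) if rarefaction_g is None else int(rarefaction_g)
    if g > min(obs_counts):
        raise ValueError(
            f"rarefaction_g={g} exceeds the smallest observation count {min(obs_counts)}"
        )

    rows = []
    for pop in pops:
        members = dataset.members(pop)
        n_alleles, n_poly_alleles, he, ho, scored, poly = [], [], [], [], 0, 0
        ar = []
        for loc in loci:
            counts = _locus_counts(dataset, loc, members)
            if not counts:
                continue
            scored += 1
            k = len(counts)
            n_alleles.append(k)
            total = sum(counts.values())
            he.append(1.0 - sum((c / total) ** 2 for c in counts.values()))
            with_data = [i for i in members if not dataset.genotypes[i][loc].missing]
            ho.append(
                sum(len(dataset.genotypes[i][loc]) >= 2 for i in with_data)
                / len(with_data)
            )
            ar.append(_rarefied_richness(counts, g))
            if k >= 2:
                poly += 1
                n_poly_alleles.append(k)
        rows.append(
            {
                "population": pop,
                "n": len(members),
                "P": 100.0 * poly / scored if scored else np.nan,
                "A": float(np.mean(n_alleles)) if n_alleles else np.nan,
                "A_p": float(np.mean(n_poly_alleles)) if n_poly_alleles else np.nan,
                "A_R": float(np.mean(ar)) if ar else np.nan,
                "H_O": float(np.mean(ho)) if ho else np.nan,
                "H_E": float(np.mean(he)) if he else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("population")

    pooled = allele_frequencies(dataset, scope="all")
    a_pooled = float(np.mean([len(f) for f in pooled.values() if f]))
    overall = table.mean(numeric_only=True)
    overall["A_pooled"] = a_pooled
    return DiversitySummary(table, overall, g)


def locus_report(dataset: MicrosatDataset, group_of: dict | None = None) -> pd.DataFrame:
    """Per-locus allele counts, size ranges (per group) and PIC.

    ``group_of`` maps population id -> group label (default: each population
    is its own group).
    """
    if group_of is None:
        group_of = {p: p for p in dataset.population_ids}
    groups = sorted(set(group_of.values()))
    rows = []
    pooled = allele_frequencies(dataset, scope="all")
    for loc in dataset.locus_names:
        row: dict = {"locus": loc}
        for grp in groups:
            members = [
                i
                for i in dataset.individuals
                if group_of.get(dataset.population_of[i]) == grp
            ]
            counts = _locus_counts(dataset, loc, members)
            per_ind = [
                len(dataset.genotypes[i][loc])
                for i in members
                if not dataset.genotypes[i][loc].missing
            ]
            if counts:
                row[f"{grp}_size_min"] = min(counts)
                row[f"{grp}_size_max"] = max(counts)
                row[f"{grp}_alleles_min"] = int(min(per_ind))
                row[f"{grp}_alleles_max"] = int(max(per_ind))
            else:
                row[f"{grp}_size_min"] = row[f"{grp}_size_max"] = np.nan
                row[f"{grp}_alleles_min"] = row[f"{grp}_alleles_max"] = np.nan
        row["PIC"] = pic(pooled[loc]) if pooled[loc] else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("locus")


_PLOIDY_LABELS = ((2, "diploid"), (4, "tetraploid"), (6, "hexaploid"), (8, "octoploid"))


def infer_ploidy(dataset: MicrosatDataset, scope=None) -> str:
    """Ploidy label from the maximum distinct-allele count.

    ``scope`` restricts to a population id or a list of individuals.
    <=2 alleles -> diploid, <=4 -> tetraploid, <=6 -> hexaploid, <=8 ->
    octoploid.
    """
    if scope is None:
        individuals = dataset.individuals
    elif isinstance(scope, str):
        individuals = dataset.members(scope)
    else:
        individuals = list(scope)
    top = dataset.max_alleles(individuals)
    if top == 0:
        raise ValueError("all genotypes missing; ploidy undefined")
    for cap, label in _PLOIDY_LABELS:
        if top <= cap:
            return label
    raise ValueError(f"more than 8 distinct alleles observed ({top})")


def ld_fisher(dataset: MicrosatDataset, locus_a: str, locus_b: str) -> float:
    """Gametic-disequilibrium screen between two loci.

    Individuals are binarized by presence of each locus's most common
    allele; returns the two-sided Fisher exact p-value of the resulting
    2x2 table.  Degenerate margins give p = 1 with a warning.
    """
    both = [
        i
        for i in dataset.individuals
        if not dataset.genotypes[i][locus_a].missing
        and not dataset.genotypes[i][locus_b].missing
    ]
    if len(both) < 2:
        raise ValueError("need >= 2 individuals scored at both loci")
    major = {}
    for loc in (locus_a, locus_b):
        counts = _locus_counts(dataset, loc, both)
        # ties broken by smaller fragment size for determinism
        major[loc] = min(sorted(counts), key=lambda a: (-counts[a], a))
    a_flags = np.array([major[locus_a] in dataset.genotypes[i][locus_a].sizes for i in both])
    b_flags = np.array([major[locus_b] in dataset.genotypes[i][locus_b].sizes for i in both])
    table = np.array(
        [
            [np.sum(a_flags & b_flags), np.sum(a_flags & ~b_flags)],
            [np.sum(~a_flags & b_flags), np.sum(~a_flags & ~b_flags)],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn(
            f"degenerate margin for {locus_a} x {locus_b}; p set to 1", UserWarning
        )
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
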