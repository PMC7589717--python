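"""Distance computations: Bruvo, Nei-Li band sharing, phenotype, geographic.

The Bruvo distance handles unequal allele-set sizes (mixed ploidy) by
averaging a *genome addition* model (the smaller set is padded with copies
of its own alleles) and a *genome loss* model (padded with the larger
set's alleles); within each model the minimal-cost matching is averaged
over every possible padding.  Sets are capped at 8 alleles, which keeps
exhaustive padding enumeration cheap.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment

from polydiff.data_model import AlleleSet, DistanceMatrix, MicrosatDataset, PopulationInfo

EARTH_RADIUS_KM = 6371.0088


def _allele_distance_matrix(a: list[int], b: list[int], repeat_unit: int) -> np.ndarray:
    xa = np.asarray(a, dtype=float)[:, None]
    xb = np.asarray(b, dtype=float)[None, :]
    steps = np.abs(xa - xb) / repeat_unit
    return 1.0 - np.power(2.0, -steps)


def _min_matching_cost(cost: np.ndarray) -> float:
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


def bruvo_pair(a: AlleleSet, b: AlleleSet, repeat_unit: int) -> float:
    """Bruvo distance between two allele sets, in [0, 1].

    Per-allele distance ``1 - 2^(-|x|)`` with x the size difference in
    repeat units; sets of equal size are matched by minimum-cost perfect
    matching, unequal sizes by the averaged addition/loss convention.
    """
    if repeat_unit <= 0:
        raise ValueError("repeat_unit must be positive")
    if a.missing or b.missing:
        raise ValueError("Bruvo distance undefined for missing genotypes")
    small, large = sorted((a.sorted(), b.sorted()), key=len)
    n_small, n_large = len(small), len(large)
    if n_small == n_large:
        cost = _allele_distance_matrix(small, large, repeat_unit)
        return _min_matching_cost(cost) / n_large

    deficit = n_large - n_small

    def padded_mean(pool: list[int]) -> float:
        # averaging over ordered paddings == multinomially weighted average
        # over padding multisets (the matching cost ignores order)
        total_cost = 0.0
        total_weight = 0.0
        for extra in itertools.combinations_with_replacement(pool, deficit):
            weight = _n_orderings(extra)
            cost = _allele_distance_matrix(small + list(extra), large, repeat_unit)
            total_cost += weight * _min_matching_cost(cost) / n_large
            total_weight += weight
        return total_cost / total_weight

    addition = padded_mean(small)
    loss = padded_mean(large)
    return 0.5 * (addition + loss)


def _n_orderings(extra: tuple) -> float:
    counts = {}
    for e in extra:
        counts[e] = counts.get(e, 0) + 1
    total = math.factorial(len(extra))
    for c in counts.values():
        total //= math.factorial(c)
    return float(total)


def bruvo_matrix(
    dataset: MicrosatDataset, level: str = "individual"
) -> DistanceMatrix:
    """Pairwise Bruvo distances, averaged over loci scored in both members.

    level="individual" gives the genotype matrix; level="population" gives
    mean inter-individual distance between populations (zero diagonal).
    Pairs with no shared scored locus get NaN with a warning.
    """
    inds = dataset.individuals
    if len(inds) < 2:
        raise ValueError("need >= 2 individuals")
    n = len(inds)
    # Bruvo is invariant under joint allele-size translation, so canonical
    # (shifted, sorted) set pairs are memoised across individuals and loci.
    cache: dict[tuple, float] = {}

    def cached_pair(sa: AlleleSet, sb: AlleleSet, unit: int) -> float:
        ta, tb = tuple(sa.sorted()), tuple(sb.sorted())
        if ta > tb:
            ta, tb = tb, ta
        base = min(ta[0], tb[0])
        key = (tuple(x - base for x in ta), tuple(x - base for x in tb), unit)
        if key not in cache:
            cache[key] = bruvo_pair(sa, sb, unit)
        return cache[key]

    per_locus: dict[str, np.ndarray] = {}
    for loc in dataset.loci:
        mat = np.full((n, n), np.nan)
        scored = [
            (i, ind) for i, ind in enumerate(inds)
            if not dataset.genotypes[ind][loc.name].missing
        ]
        for (i, ind_i), (j, ind_j) in itertools.combinations(scored, 2):
            d = cached_pair(
                dataset.genotypes[ind_i][loc.name],
                dataset.genotypes[ind_j][loc.name],
                loc.repeat_unit,
            )
            mat[i, j] = mat[j, i] = d
        np.fill_diagonal(mat, 0.0)
        per_locus[loc.name] = mat

    stacked = np.stack(list(per_locus.values()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(stacked, axis=0)
    if np.isnan(values).any():
        warnings.warn("some pairs share no scored locus; distances set to NaN")
    ind_matrix = DistanceMatrix(inds, values)
    if level == "individual":
        return ind_matrix
    if level != "population":
        raise ValueError(f"unknown level {level!r}")

    pops = dataset.population_ids
    out = np.zeros((len(pops), len(pops)))
    idx = {ind: i for i, ind in enumerate(inds)}
    for a, pa in enumerate(pops):
        for b in range(a + 1, len(pops)):
            rows = [idx[i] for i in dataset.members(pa)]
            cols = [idx[i] for i in dataset.members(pops[b])]
            block = values[np.ix_(rows, cols)]
            out[a, b] = out[b, a] = float(np.nanmean(block))
    return DistanceMatrix(pops, out)


def genetic_similarity(fragments_i, fragments_j) -> float:
    """Band-sharing similarity GS = 2 * N_ij / (N_i + N_j), in [0, 1]."""
    si, sj = set(fragments_i), set(fragments_j)
    if not si and not sj:
        raise ValueError("both fragment sets empty; GS undefined")
    return 2.0 * len(si & sj) / (len(si) + len(sj))


def nei_li_distance(fragments_x, fragments_y) -> float:
    """Nei-Li band-sharing distance, the complement 1 - GS."""
    return 1.0 - genetic_similarity(fragments_x, fragments_y)


def fragment_set(dataset: MicrosatDataset, individual: str) -> set:
    """All observed (locus, allele) bands of an individual."""
    return {
        (loc, allele)
        for loc, aset in dataset.genotypes[individual].items()
        for allele in aset.sizes
    }


def nei_li_matrix(dataset: MicrosatDataset) -> DistanceMatrix:
    """Pairwise Nei-Li distances on pooled band-presence profiles."""
    inds = dataset.individuals
    frags = {i: fragment_set(dataset, i) for i in inds}
    n = len(inds)
    values = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        values[a, b] = values[b, a] = nei_li_distance(frags[inds[a]], frags[inds[b]])
    return DistanceMatrix(inds, values)


def phenotype_euclidean(records, level: str = "population") -> DistanceMatrix:
    """Euclidean distance between population means of z-scored traits.

    Replicate measurements are averaged per plant; each trait is then
    standardized over all plants (mean 0, sd 1); zero-variance traits are
    excluded with a warning.
    """
    from polydiff.data_model import FACTOR_COLUMNS, plant_level, records_to_frame

    frame = records_to_frame(list(records)) if not hasattr(records, "columns") else records.copy()
    frame = plant_level(frame)
    traits = [c for c in frame.columns if c not in FACTOR_COLUMNS]
    keep = []
    for t in traits:
        sd = frame[t].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"trait {t!r} has zero variance; excluded")
            continue
        frame[t] = (frame[t] - frame[t].mean()) / sd
        keep.append(t)
    if not keep:
        raise ValueError("no trait with positive variance")
    means = frame.groupby("population", sort=False)[keep].mean()
    if len(means) < 2:
        raise ValueError("need >= 2 populations")
    x = means.to_numpy()
    diff = x[:, None, :] - x[None, :, :]
    values = np.sqrt(np.nansum(diff**2, axis=2))
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix([str(p) for p in means.index], values)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two points, km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def geographic_distance(a: PopulationInfo, b: PopulationInfo) -> float:
    """Haversine distance between two sampling sites, km."""
    return haversine_km(a.latitude, a.longitude, b.latitude, b.longitude)


def geographic_matrix(populations) -> DistanceMatrix:
    pops = list(populations)
    n = len(pops)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        values[i, j] = values[j, i] = geographic_distance(pops[i], pops[j])
    return DistanceMatrix([p.id for p in pops], values)
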