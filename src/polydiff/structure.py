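"""Ordination, tree building and trait-distribution screening.

PCoA is classical metric scaling (double-centered -D^2/2, eigendecomposed);
negative eigenvalues are dropped and reported, not corrected, since Bruvo
matrices at this scale are near-Euclidean.  Neighbor joining follows the
Saitou-Nei agglomeration with the Studier-Keppler Q criterion, ties broken
by the lexicographically smallest pair of cluster labels and negative
branch lengths clamped to zero with the deficit moved onto the sister
branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from polydiff.data_model import (
    FACTOR_COLUMNS,
    DistanceMatrix,
    plant_level,
    records_to_frame,
)
from polydiff.distances import phenotype_euclidean


# ---------------------------------------------------------------------------
# principal coordinates


@dataclass
class PcoaResult:
    """Classical-scaling coordinates with eigenvalue bookkeeping."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    n_negative: int
    negative_magnitude: float


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Principal coordinates analysis of a distance matrix.

    Coordinates are eigenvectors scaled by the square root of their
    (positive) eigenvalues; axes with non-positive eigenvalues are dropped
    and their count/magnitude reported.
    """
    values = np.asarray(d.values, dtype=float)
    n = len(d.labels)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (values**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0))
    positive = eigvals > tol
    n_negative = int(np.sum(eigvals < -tol))
    negative_magnitude = float(-eigvals[eigvals < -tol].sum()) if n_negative else 0.0

    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)
    if n_axes is not None:
        coords = coords[:, :n_axes]
        pos_vals_kept = pos_vals[:n_axes]
    else:
        pos_vals_kept = pos_vals
    total = pos_vals.sum() if pos_vals.size else 1.0
    frame = pd.DataFrame(
        coords,
        index=d.labels,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return PcoaResult(
        coordinates=frame,
        eigenvalues=pos_vals_kept,
        proportion_explained=pos_vals_kept / total,
        n_negative=n_negative,
        negative_magnitude=negative_magnitude,
    )


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(d: DistanceMatrix):
    """Neighbor-joining tree from a distance matrix (dendropy Tree).

    Deterministic: Q-criterion ties are broken by the lexicographically
    smallest (sorted) pair of cluster labels.  Negative branch lengths are
    clamped at 0 and the deficit transferred to the sister branch.
    """
    import dendropy

    labels = list(d.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 labels")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes = {}
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes[label] = node
    # cluster label -> sorted leaf-name tuple, for deterministic tie-breaks
    sig = {label: (label,) for label in labels}
    dist = {
        (a, b): float(d.loc(a, b))
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }

    def get(a, b):
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    active = list(labels)
    counter = 0
    while len(active) > 2:
        m = len(active)
        totals = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * get(a, b) - totals[a] - totals[b]
                key = tuple(sorted((sig[a], sig[b])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, a, b)
        _, _, a, b = best
        dab = get(a, b)
        la = 0.5 * dab + (totals[a] - totals[b]) / (2.0 * (m - 2))
        lb = dab - la
        # clamp negatives, moving the deficit to the sister branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = dendropy.Node()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.edge.length = la
        nb.edge.length = lb
        parent.add_child(na)
        parent.add_child(nb)
        new_label = f"__cluster{counter}"
        counter += 1
        nodes[new_label] = parent
        sig[new_label] = tuple(sorted(sig[a] + sig[b]))
        for c in active:
            if c in (a, b):
                continue
            dist[(new_label, c)] = 0.5 * (get(a, c) + get(b, c) - dab)
        active = [c for c in active if c not in (a, b)] + [new_label]

    if len(active) == 2:
        a, b = active
        length = max(get(a, b), 0.0)
        na, nb = nodes[a], nodes[b]
        if na.is_leaf() and not nb.is_leaf():
            na, nb = nb, na
        nb.edge.length = length
        na.add_child(nb)
        root = na
    else:
        root = nodes[active[0]]
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_to_newick(tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# bootstrap-supported hierarchical clustering of phenotypes


@dataclass
class HclustResult:
    """Average-linkage dendrogram with bootstrap node support (percent)."""

    linkage: np.ndarray
    labels: list
    support: dict  # frozenset of population labels -> percent

    def node_sets(self) -> list:
        return sorted(self.support, key=len)


def _linkage_clades(z: np.ndarray, labels: list) -> set:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    clades = set()
    for k, (i, j, _, _) in enumerate(z[:, :4]):
        merged = members[int(i)] | members[int(j)]
        members[n + k] = merged
        clades.add(merged)
    return clades


def hclust_phenotypes(
    records, n_bootstrap: int = 100, seed: int = 0
) -> HclustResult:
    """Average-linkage clustering of populations on standardized traits.

    Node support is the percentage of trait-resampled bootstrap replicates
    (traits drawn with replacement) whose dendrogram contains the node's
    population set.
    """
    frame = records_to_frame(list(records)) if not hasattr(records, "columns") else records
    d = phenotype_euclidean(frame)
    if len(d.labels) < 3:
        raise ValueError("need >= 3 populations")
    z = hierarchy.linkage(d.condensed(), method="average")
    clades = _linkage_clades(z, d.labels)

    support = {clade: 0 for clade in clades}
    if n_bootstrap > 0:
        factors = [c for c in FACTOR_COLUMNS if c in frame.columns]
        traits = [c for c in frame.columns if c not in FACTOR_COLUMNS]
        rng = np.random.default_rng(seed)
        for _ in range(n_bootstrap):
            chosen = list(rng.choice(traits, size=len(traits), replace=True))
            boot = frame[factors].copy()
            for idx, t in enumerate(chosen):
                boot[f"bs{idx}"] = frame[t]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    db = phenotype_euclidean(boot)
                except ValueError:
                    continue
            zb = hierarchy.linkage(db.reorder(d.labels).condensed(), method="average")
            boot_clades = _linkage_clades(zb, d.labels)
            for clade in clades:
                if clade in boot_clades:
                    support[clade] += 1
        support = {c: 100.0 * k / n_bootstrap for c, k in support.items()}
    else:
        support = {c: float("nan") for c in clades}
    return HclustResult(z, d.labels, support)


# ---------------------------------------------------------------------------
# phenotype PCA


@dataclass
class PcaResult:
    """Correlation-matrix PCA of traits."""

    loadings: pd.DataFrame  # traits x components, unit-norm columns
    sdev: np.ndarray
    proportion: np.ndarray
    cumulative: np.ndarray
    scores: pd.DataFrame


def pheno_pca(records) -> PcaResult:
    """PCA on the trait correlation matrix (z-scored plant-mean traits).

    Component signs are fixed so each component's largest-magnitude loading
    is negative, matching the orientation convention of the reference
    decomposition; orientation is cosmetic and carries no information.
    """
    frame = records_to_frame(list(records)) if not hasattr(records, "columns") else records.copy()
    frame = plant_level(frame)
    traits = [c for c in frame.columns if c not in FACTOR_COLUMNS]
    data = frame[traits].dropna()
    if len(data) < 3 or len(traits) < 2:
        raise ValueError("need >= 3 complete plants and >= 2 traits")
    keep = [t for t in traits if data[t].std(ddof=1) > 0]
    dropped = set(traits) - set(keep)
    if dropped:
        warnings.warn(f"zero-variance traits excluded: {sorted(dropped)}")
    z = (data[keep] - data[keep].mean()) / data[keep].std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = np.clip(eigvals[order], 0, None), eigvecs[:, order]
    for c in range(eigvecs.shape[1]):
        imax = int(np.argmax(np.abs(eigvecs[:, c])))
        if eigvecs[imax, c] > 0:
            eigvecs[:, c] = -eigvecs[:, c]
    comp_names = [f"PC{i + 1}" for i in range(len(eigvals))]
    loadings = pd.DataFrame(eigvecs, index=keep, columns=comp_names)
    proportion = eigvals / eigvals.sum()
    scores = pd.DataFrame(
        z.to_numpy() @ eigvecs, index=data.index, columns=comp_names
    )
    return PcaResult(
        loadings=loadings,
        sdev=np.sqrt(eigvals),
        proportion=proportion,
        cumulative=np.cumsum(proportion),
        scores=scores,
    )


# ---------------------------------------------------------------------------
# bimodality screening


@dataclass
class BimodalityResult:
    classification: str  # "unimodal" | "bimodal"
    bic_difference: float  # BIC(1 component) - BIC(2 components)
    weights: tuple
    means: tuple


def bimodality_screen(
    values, bic_margin: float = 10.0, min_weight: float = 0.1, seed: int = 0
) -> BimodalityResult:
    """Screen a trait sample for bimodality via Gaussian-mixture BIC.

    Declares "bimodal" when the 2-component fit beats the 1-component fit
    by more than ``bic_margin`` BIC units and both mixture weights are at
    least ``min_weight``.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 20:
        raise ValueError("need n >= 20")
    if np.ptp(x) == 0:
        return BimodalityResult("unimodal", 0.0, (1.0,), (float(x[0]),))
    x = x.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=seed).fit(x)
    gm2 = GaussianMixture(2, n_init=3, random_state=seed).fit(x)
    diff = float(gm1.bic(x) - gm2.bic(x))
    weights = tuple(float(w) for w in gm2.weights_)
    means = tuple(float(m) for m in gm2.means_.ravel())
    bimodal = diff > bic_margin and min(weights) >= min_weight
    return BimodalityResult(
        "bimodal" if bimodal else "unimodal", diff, weights, means
    )
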