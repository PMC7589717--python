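"""Mantel correlation between distance matrices with permutation inference.

Used here for isolation by distance: pairwise genetic differentiation
against great-circle geographic distance.  The permutation null jointly
permutes rows and columns of the second matrix; the reported p-value uses
the add-one correction so it can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from polydiff.data_model import DistanceMatrix


@dataclass
class MantelResult:
    r: float
    r_squared: float
    p: float
    n_perm: int
    seed: int
    alternative: str

    def __repr__(self) -> str:
        return f"<MantelResult r={self.r:.4f} r2={self.r_squared:.4f} p={self.p:.4g}>"


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> MantelResult:
    """Mantel test between two distance matrices over the same labels.

    r is the Pearson correlation of upper-triangle entries; the null
    distribution comes from ``n_perm`` joint row/column permutations of
    ``d2``; p = (1 + #extreme) / (1 + n_perm).  "two-sided" compares |r|,
    "greater"/"less" the signed r.
    """
    if sorted(d1.labels) != sorted(d2.labels):
        raise ValueError("matrices must share the same labels")
    n = len(d1.labels)
    if n < 4:
        raise ValueError("need >= 4 labels")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    m2 = d2.reorder(d1.labels).values
    m1 = d1.values
    iu = np.triu_indices(n, k=1)
    x = m1[iu]
    if np.std(x) == 0 or np.std(m2[iu]) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    xc = x - x.mean()
    xnorm = np.sqrt(np.sum(xc**2))

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        yc = y - y.mean()
        return float(np.sum(xc * yc) / (xnorm * np.sqrt(np.sum(yc**2))))

    r_obs = corr(m2)
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = corr(m2[np.ix_(perm, perm)])
        if alternative == "two-sided":
            hit = abs(r_perm) >= abs(r_obs) - 1e-15
        elif alternative == "greater":
            hit = r_perm >= r_obs - 1e-15
        else:
            hit = r_perm <= r_obs + 1e-15
        extreme += hit
    p = (1 + extreme) / (1 + n_perm)
    return MantelResult(r_obs, r_obs**2, float(p), n_perm, seed, alternative)
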