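"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: matchings are
enumerated as permutations, paddings as ordered products, p-values as
hypergeometric tail sums, and Duncan groupings as direct pairwise range
comparisons.
"""

import itertools
import math

from scipy import stats


def bruvo_brute(a, b, repeat_unit):
    """Exhaustive Bruvo distance: all ordered paddings x all permutations."""
    a, b = sorted(a), sorted(b)
    if len(a) > len(b):
        a, b = b, a

    def allele_d(x, y):
        return 1.0 - 2.0 ** (-abs(x - y) / repeat_unit)

    def match_cost(left, right):
        k = len(right)
        best = math.inf
        for perm in itertools.permutations(range(k)):
            cost = sum(allele_d(left[i], right[perm[i]]) for i in range(k)) / k
            best = min(best, cost)
        return best

    deficit = len(b) - len(a)
    if deficit == 0:
        return match_cost(a, b)

    def model_mean(pool):
        costs = [
            match_cost(list(a) + list(extra), b)
            for extra in itertools.product(pool, repeat=deficit)
        ]
        return sum(costs) / len(costs)

    return 0.5 * (model_mean(a) + model_mean(b))


def fisher_two_sided(table):
    """Two-sided Fisher exact p: hypergeometric tail sum over tables with
    probability <= the observed table's."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    hg = stats.hypergeom(n, row1, col1)
    p_obs = hg.pmf(a)
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        p = hg.pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def duncan_groups(means, n, ms_within, df_within, alpha=0.05):
    """Direct Duncan grouping on sorted means: a pair differs iff its range
    exceeds the least significant range for its span and no enclosing
    non-significant range protects it."""
    order = sorted(range(len(means)), key=lambda i: -means[i])
    sorted_means = [means[i] for i in order]
    k = len(means)

    def lsr(span):
        protection = 1.0 - (1.0 - alpha) ** (span - 1)
        q = stats.studentized_range.ppf(1.0 - protection, span, df_within)
        return q * math.sqrt(ms_within / n)

    nonsig = set()
    # mark every range whose stretch is within its LSR, outside-in
    spans = sorted(
        ((i, j) for i in range(k) for j in range(i + 1, k)),
        key=lambda ij: ij[0] - ij[1],
    )
    protected = set()
    for i, j in spans:
        if any(a <= i and j <= b for (a, b) in protected):
            nonsig.add((i, j))
            continue
        if sorted_means[i] - sorted_means[j] <= lsr(j - i + 1):
            nonsig.add((i, j))
            protected.add((i, j))
    # significant pairs in original indexing
    sig = set()
    for i in range(k):
        for j in range(i + 1, k):
            if (i, j) not in nonsig:
                sig.add(frozenset((order[i], order[j])))
    return sig
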