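"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: the rank
product is recomputed per gene from first principles and the permutation
null is enumerated exhaustively over every within-column rank permutation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_LOG_TOL = 1e-9


def rank_by_hand(column: list[float], descending: bool) -> list[float]:
    """Average ranks of one ratio column, rank 1 = most extreme."""
    key = [(-v if descending else v) for v in column]
    order = sorted(range(len(key)), key=lambda i: key[i])
    ranks = [0.0] * len(key)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and key[order[j + 1]] == key[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def rank_product_by_hand(ratios: np.ndarray, direction: str = "up") -> np.ndarray:
    """Geometric mean of per-column ranks, gene by gene."""
    n, k = ratios.shape
    cols = [rank_by_hand(list(ratios[:, j]), direction == "up") for j in range(k)]
    out = np.empty(n)
    for g in range(n):
        prod = 1.0
        for j in range(k):
            prod *= cols[j][g]
        out[g] = prod ** (1.0 / k)
    return out


def exhaustive_permutation_p(
    ratios: np.ndarray, direction: str = "up"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact pooled permutation null by full enumeration.

    Enumerates every combination of within-column permutations of the
    observed rank values ((n!)^K configurations), and for each observed
    rank product returns the exact mean and standard deviation (over
    configurations) of ``count/n`` where count is the number of permuted
    rank products at or below it.

    Returns (p_exact, sd_count_fraction, observed_rp).
    """
    n, k = ratios.shape
    cols = [rank_by_hand(list(ratios[:, j]), direction == "up") for j in range(k)]
    observed_log = np.log(rank_product_by_hand(ratios, direction))

    count_sums = np.zeros(n)
    count_sqsums = np.zeros(n)
    n_configs = 0
    for perm_cols in itertools.product(*[itertools.permutations(c) for c in cols]):
        n_configs += 1
        perm_log = sorted(
            sum(math.log(perm_cols[j][g]) for j in range(k)) / k for g in range(n)
        )
        for g in range(n):
            c = np.searchsorted(perm_log, observed_log[g] + _LOG_TOL, side="right")
            count_sums[g] += c / n
            count_sqsums[g] += (c / n) ** 2
    mean = count_sums / n_configs
    var = count_sqsums / n_configs - mean**2
    return mean, np.sqrt(np.maximum(var, 0.0)), np.exp(observed_log)


def recount_representation(
    de, annotation, code: str, direction: str, annotated_only: bool = False
):
    """Recount the four representation numbers directly from raw DE calls."""
    universe = set(de["gene_id"])
    if annotated_only:
        universe &= set(annotation.gene_ids)
    members = annotation.genes_in_category(code) & universe
    regulated = set(de.loc[de["call"] == direction, "gene_id"]) & universe
    n_xp = len(members & regulated)
    n_xt = len(members)
    n_ap = len(regulated)
    n_at = len(universe)
    ratio = (n_xp / n_xt) / (n_ap / n_at) if n_xt and n_ap else math.nan
    return n_xp, n_xt, n_ap, n_at, ratio
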