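"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible — explicit Python loops,
no shared code with the package — so that agreement between an oracle and
the corresponding package routine is meaningful evidence of correctness.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def afd_bruteforce(freqs1: dict, freqs2: dict) -> float:
    """Half the sum of absolute frequency differences over the allele union."""
    total = 0.0
    for allele in set(freqs1) | set(freqs2):
        total += abs(freqs1.get(allele, 0.0) - freqs2.get(allele, 0.0))
    return total / 2.0


def mafd_bruteforce(alleles_by_population: dict, locus_index: int) -> float:
    """Mean AFD at one locus over all unordered population pairs.

    ``alleles_by_population`` maps population id -> (n, L) int array.
    Frequencies are counted by hand from the raw allele columns.
    """
    spectra = {}
    for pop, mat in alleles_by_population.items():
        column = [int(v) for v in mat[:, locus_index]]
        counts: dict = {}
        for v in column:
            counts[v] = counts.get(v, 0) + 1
        spectra[pop] = {a: c / len(column) for a, c in counts.items()}
    values = [
        afd_bruteforce(spectra[a], spectra[b])
        for a, b in combinations(sorted(spectra), 2)
    ]
    return sum(values) / len(values)


def squared_distance(h1, h2) -> float:
    return float(sum((int(a) - int(b)) ** 2 for a, b in zip(h1, h2)))


def amova_phist_bruteforce(pop_a: np.ndarray, pop_b: np.ndarray) -> float:
    """Two-level AMOVA fixation index from explicit sums of squares.

    Haplotype rows; distance = sum of squared repeat differences.  Written
    straight from the standard two-level variance-component formulas with
    explicit double loops.
    """
    groups = [np.asarray(pop_a), np.asarray(pop_b)]
    haplotypes = [tuple(row) for g in groups for row in g]
    n = len(haplotypes)
    sizes = [len(g) for g in groups]

    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += squared_distance(haplotypes[i], haplotypes[j])
    ss_total /= n

    ss_within = 0.0
    for g in groups:
        sub = 0.0
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                sub += squared_distance(g[i], g[j])
        ss_within += sub / len(g)

    ss_among = ss_total - ss_within
    df_among = len(groups) - 1
    df_within = n - len(groups)
    ms_among = ss_among / df_among
    sigma_within = ss_within / df_within
    n0 = (n - sum(s * s for s in sizes) / n) / df_among
    sigma_among = (ms_among - sigma_within) / n0
    if sigma_among + sigma_within == 0:
        return 0.0
    return sigma_among / (sigma_among + sigma_within)


def pearson_bruteforce(x, y) -> float:
    """Product-moment correlation from first principles."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (
        sum((a - mx) ** 2 for a in x) ** 0.5
        * sum((b - my) ** 2 for b in y) ** 0.5
    )
    return num / den


def spearman_bruteforce(x, y) -> float:
    """Rank correlation: Pearson on midranks."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    return pearson_bruteforce(midranks(list(x)), midranks(list(y)))
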