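"""AMOVA-based pairwise genetic distances between populations of Y-STR haplotypes.

Population differentiation is quantified with a two-level analysis of
molecular variance (AMOVA) on inter-haplotype distances.  With the default
sum-of-squared-repeat-difference metric the resulting fixation index is the
Rst analogue appropriate for STRs under stepwise mutation; with the Hamming
metric (count of differing loci) it is the Fst analogue.  For two
populations A, B with nA and nB haplotypes and squared distances d_ij:

    SS(total)  = (1/N) * sum_{i<j} d_ij,             N = nA + nB
    SS(within) = (1/nA) * sum_{i<j in A} d_ij + (1/nB) * sum_{i<j in B} d_ij
    SS(among)  = SS(total) - SS(within)

    sigma2_w = SS(within) / (N - 2)
    n0       = (N - (nA^2 + nB^2)/N) / (P - 1),      P = 2
    sigma2_a = (SS(among)/(P - 1) - sigma2_w) / n0
    Phi_st   = sigma2_a / (sigma2_a + sigma2_w)

Variance-component estimates can make Phi_st slightly negative for
undifferentiated populations; negatives are reported as computed and only
clamped downstream (at MDS input) where a dissimilarity is required.

Significance comes from a permutation test: haplotypes are reshuffled
between the two populations keeping sample sizes, and the p-value is
(#{permuted Phi >= observed} + 1) / (n_perm + 1).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .iohap import HaplotypeTable, MarkerPanel

METRICS = ("sum_squared_size_diff", "hamming")

_PERM_CHUNK = 512  # permutations processed per BLAS block


@dataclass(frozen=True)
class HaplotypeDistanceSpec:
    """Distance metric + marker panel defining one analysis."""

    loci: MarkerPanel
    metric: str = "sum_squared_size_diff"

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValidationError(f"metric must be one of {METRICS}, got {self.metric!r}")


def haplotype_distance(h1: Mapping, h2: Mapping, spec: HaplotypeDistanceSpec) -> float:
    """Distance between two haplotypes over the panel loci.

    ``h1``/``h2`` map locus name to an integer repeat count (or an
    integer-state allele call).  Default metric: sum of squared
    repeat-count differences; ``hamming`` counts differing loci.
    """
    diffs = []
    for locus in spec.loci:
        try:
            a, b = h1[locus], h2[locus]
        except KeyError as exc:
            raise ValidationError(f"haplotype lacks panel locus {exc.args[0]!r}") from exc
        a = a.value if hasattr(a, "value") else a
        b = b.value if hasattr(b, "value") else b
        if not (isinstance(a, (int, np.integer)) and isinstance(b, (int, np.integer))):
            raise ValidationError(f"non-integer allele at {locus}; run QC first")
        diffs.append(int(a) - int(b))
    d = np.asarray(diffs, dtype=float)
    if spec.metric == "hamming":
        return float(np.count_nonzero(d))
    return float(np.dot(d, d))


def _pair_distance_matrix(x: np.ndarray, metric: str) -> np.ndarray:
    """Square inter-haplotype distance matrix for an allele matrix."""
    if metric == "hamming":
        condensed = pdist(x, "hamming") * x.shape[1]
    else:
        condensed = pdist(x, "sqeuclidean")
    return squareform(condensed)


def _phist_from_within_sums(
    within_a: float, within_b: float, total: float, n_a: int, n_b: int
) -> float:
    """Two-level AMOVA Phi_st from pair-sum aggregates.

    ``within_a``/``within_b``/``total`` are sums of d over unordered pairs
    within A, within B, and over all haplotypes respectively.
    """
    n = n_a + n_b
    ss_within = within_a / n_a + within_b / n_b
    ss_total = total / n
    ss_among = ss_total - ss_within
    if n <= 2:
        raise ValidationError("AMOVA needs more than two haplotypes in total")
    sigma_w = ss_within / (n - 2)
    n0 = (n - (n_a * n_a + n_b * n_b) / n) / 1.0  # P - 1 = 1
    sigma_a = (ss_among / 1.0 - sigma_w) / n0
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return float(sigma_a / denom)


def _phist_from_matrix(d: np.ndarray, n_a: int) -> float:
    """Phi_st when the first ``n_a`` rows of ``d`` are population A."""
    n = d.shape[0]
    within_a = d[:n_a, :n_a].sum() / 2.0
    within_b = d[n_a:, n_a:].sum() / 2.0
    total = d.sum() / 2.0
    return _phist_from_within_sums(within_a, within_b, total, n_a, n - n_a)


def _stacked_alleles(
    table: HaplotypeTable, pop_a: str, pop_b: str, spec: HaplotypeDistanceSpec
) -> tuple:
    mask_a = table.population_mask(pop_a)
    mask_b = table.population_mask(pop_b)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 2 or n_b < 2:
        raise ValidationError(
            f"populations need >= 2 haplotypes each (got {pop_a}:{n_a}, {pop_b}:{n_b})"
        )
    x = table.numeric_matrix(list(spec.loci))
    return np.vstack([x[mask_a], x[mask_b]]), n_a, n_b


def pairwise_phist(
    table: HaplotypeTable, pop_a: str, pop_b: str, spec: HaplotypeDistanceSpec
) -> float:
    """AMOVA Phi_st between two populations (symmetric; may be slightly < 0)."""
    x, n_a, _ = _stacked_alleles(table, pop_a, pop_b, spec)
    return _phist_from_matrix(_pair_distance_matrix(x, spec.metric), n_a)


def _pair_seed_sequence(seed: int, pop_a: str, pop_b: str) -> np.random.SeedSequence:
    """Reproducible per-pair RNG stream keyed by (seed, sorted pair ids)."""
    lo, hi = sorted([str(pop_a), str(pop_b)])
    return np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(lo.encode()), zlib.crc32(hi.encode())]
    )


def _permuted_phists(
    d: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Phi_st for ``n_perm`` random relabelings, vectorized in chunks."""
    n = d.shape[0]
    n_b = n - n_a
    grand_total = d.sum()  # ordered pairs, = 2 * pair sum
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(_PERM_CHUNK, n_perm - done)
        za = np.zeros((k, n))
        for i in range(k):
            za[i, rng.permutation(n)[:n_a]] = 1.0
        m = za @ d                       # (k, n): sum_{i in A} d_ij per column j
        row_a = m.sum(axis=1)            # sum_{i in A, j in all}
        within_a2 = (m * za).sum(axis=1)  # ordered within-A sum
        within_b2 = grand_total - 2.0 * row_a + within_a2
        for i in range(k):
            out[done + i] = _phist_from_within_sums(
                within_a2[i] / 2.0, within_b2[i] / 2.0, grand_total / 2.0, n_a, n_b
            )
        done += k
    return out


def permutation_test(
    table: HaplotypeTable,
    pop_a: str,
    pop_b: str,
    spec: HaplotypeDistanceSpec,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation p-value for Phi_st between two populations.

    Haplotypes are reshuffled between the populations keeping sample sizes;
    p = (#{permuted Phi >= observed} + 1) / (n_perm + 1), so p is never 0.
    The RNG stream is keyed to the sorted pair ids, making the p-value
    independent of computation order.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    x, n_a, _ = _stacked_alleles(table, pop_a, pop_b, spec)
    d = _pair_distance_matrix(x, spec.metric)
    observed = _phist_from_matrix(d, n_a)
    rng = np.random.default_rng(_pair_seed_sequence(seed, pop_a, pop_b))
    permuted = _permuted_phists(d, n_a, n_perm, rng)
    return float((np.count_nonzero(permuted >= observed - 1e-12) + 1) / (n_perm + 1))


@dataclass
class PairwiseDistanceMatrix:
    """Symmetric population x population Phi_st matrix with permutation p-values."""

    populations: list
    d: np.ndarray
    p: np.ndarray
    n_perm: int
    panel: str
    metric: str = "sum_squared_size_diff"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        self.p = np.asarray(self.p, float)
        k = len(self.populations)
        if self.d.shape != (k, k) or self.p.shape != (k, k):
            raise ValidationError("matrix shapes do not match population count")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValidationError("distance matrix must be symmetric with zero diagonal")
        off = ~np.eye(k, dtype=bool)
        if k > 1 and (np.any(self.p[off] < 0) or np.any(self.p[off] > 1)):
            raise ValidationError("p-values must lie in [0, 1]")

    def pair_index(self) -> list:
        return list(combinations(range(len(self.populations)), 2))

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in pair order."""
        return np.array([self.d[i, j] for i, j in self.pair_index()])

    def entry(self, pop_a: str, pop_b: str) -> tuple:
        i = self.populations.index(pop_a)
        j = self.populations.index(pop_b)
        return float(self.d[i, j]), float(self.p[i, j])

    # -- serialization ------------------------------------------------------

    def to_phylip(self, path) -> None:
        """Square PHYLIP distance-matrix format (relaxed names)."""
        width = max(10, max(len(str(p)) for p in self.populations) + 2)
        with open(path, "w") as fh:
            fh.write(f"{len(self.populations)}\n")
            for i, pop in enumerate(self.populations):
                row = " ".join(f"{v:.6f}" for v in self.d[i])
                fh.write(f"{str(pop):<{width}}{row}\n")

    def to_tsv(self, path) -> None:
        """Long form: one row per unordered pair with distance and p-value."""
        rows = [
            {
                "pop_a": self.populations[i],
                "pop_b": self.populations[j],
                "distance": self.d[i, j],
                "p_value": self.p[i, j],
            }
            for i, j in self.pair_index()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def distance_matrix(
    table: HaplotypeTable,
    panel: MarkerPanel,
    n_perm: int = 10_000,
    seed: int = 0,
    metric: str = "sum_squared_size_diff",
) -> PairwiseDistanceMatrix:
    """All-pairs Phi_st matrix with permutation p-values.

    Per-pair RNG streams are derived from (seed, sorted pair ids), so the
    matrix is reproducible regardless of the order pairs are computed in.
    """
    pops = table.populations
    if len(pops) < 2:
        raise ValidationError("distance matrix needs >= 2 populations")
    spec = HaplotypeDistanceSpec(panel, metric)
    k = len(pops)
    d = np.zeros((k, k))
    p = np.zeros((k, k))
    x = table.numeric_matrix(list(panel))
    masks = {pop: table.population_mask(pop) for pop in pops}
    for i, j in combinations(range(k), 2):
        a, b = pops[i], pops[j]
        n_a, n_b = int(masks[a].sum()), int(masks[b].sum())
        if n_a < 2 or n_b < 2:
            raise ValidationError(f"population {a if n_a < 2 else b} has < 2 haplotypes")
        stacked = np.vstack([x[masks[a]], x[masks[b]]])
        dm = _pair_distance_matrix(stacked, metric)
        phist = _phist_from_matrix(dm, n_a)
        rng = np.random.default_rng(_pair_seed_sequence(seed, a, b))
        permuted = _permuted_phists(dm, n_a, n_perm, rng)
        pval = (np.count_nonzero(permuted >= phist - 1e-12) + 1) / (n_perm + 1)
        d[i, j] = d[j, i] = phist
        p[i, j] = p[j, i] = pval
    return PairwiseDistanceMatrix(list(pops), d, p, n_perm, panel.name, metric)


@dataclass
class MatrixComparison:
    """Two distance matrices on the same populations, pair by pair.

    Pairs are ordered ascending by the reference-matrix distance (the
    line-chart convention for panel comparisons); ``frac_increased`` is the
    share of pairs where the alternative matrix exceeds the reference
    beyond the tie tolerance.
    """

    pairs: list
    d_ref: np.ndarray
    d_alt: np.ndarray
    frac_increased: float
    frac_decreased: float
    frac_tied: float
    ref_name: str = "ref"
    alt_name: str = "alt"

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "pop_a": [a for a, _ in self.pairs],
                "pop_b": [b for _, b in self.pairs],
                "d_ref": self.d_ref,
                "d_alt": self.d_alt,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> dict:
        return {
            "ref": self.ref_name,
            "alt": self.alt_name,
            "n_pairs": len(self.pairs),
            "frac_increased": self.frac_increased,
            "frac_decreased": self.frac_decreased,
            "frac_tied": self.frac_tied,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2, sort_keys=True) + "\n")


def compare_distance_matrices(
    ref: PairwiseDistanceMatrix,
    alt: PairwiseDistanceMatrix,
    tie_tol: float = 1e-12,
) -> MatrixComparison:
    """Pair-by-pair comparison of two distance matrices.

    Both matrices must cover the same populations; pairs are sorted
    ascending by reference distance and classified as increased, decreased
    or tied (|delta| <= ``tie_tol``) in the alternative matrix.
    """
    if set(ref.populations) != set(alt.populations):
        raise ValidationError("matrices cover different population sets")
    alt_index = {p: i for i, p in enumerate(alt.populations)}
    pairs, d_ref, d_alt = [], [], []
    for i, j in ref.pair_index():
        a, b = ref.populations[i], ref.populations[j]
        pairs.append((a, b))
        d_ref.append(ref.d[i, j])
        d_alt.append(alt.d[alt_index[a], alt_index[b]])
    order = np.argsort(d_ref, kind="stable")
    d_ref = np.asarray(d_ref)[order]
    d_alt = np.asarray(d_alt)[order]
    pairs = [pairs[k] for k in order]
    delta = d_alt - d_ref
    n = len(pairs)
    inc = float(np.count_nonzero(delta > tie_tol) / n)
    dec = float(np.count_nonzero(delta < -tie_tol) / n)
    return MatrixComparison(
        pairs, d_ref, d_alt, inc, dec, 1.0 - inc - dec, ref.panel, alt.panel
    )
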