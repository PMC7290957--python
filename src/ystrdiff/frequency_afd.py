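"""Allele-frequency spectra, the AFD statistic, mAFD ranking and sliding panels.

The allele frequency difference (AFD) between two populations at one locus is
half the L1 distance between their allele-frequency vectors, taken over the
union of alleles observed in either population:

    AFD = 1/2 * sum_i |f_i1 - f_i2|

It ranges from 0 (identical spectra) to 1 (disjoint allele sets).  The mean
of the AFD over all unordered population pairs (mAFD) scores how strongly a
single locus differentiates a collection of populations; ranking loci by
mAFD and sliding a fixed-size window down the ranking yields a series of
marker panels of decreasing differentiation power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .iohap import HaplotypeTable, MarkerPanel

_NORMALIZATION_TOL = 1e-12


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Relative allele frequencies for one locus in one population."""

    locus: str
    population: str
    freqs: Mapping
    n_samples: int

    def __post_init__(self) -> None:
        total = float(sum(self.freqs.values()))
        if self.freqs and abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"frequencies at {self.locus}/{self.population} sum to {total}, not 1"
            )
        if any(f < 0 or f > 1 for f in self.freqs.values()):
            raise ValidationError("frequencies must lie in [0, 1]")

    def frequency(self, allele) -> float:
        return float(self.freqs.get(allele, 0.0))


def allele_frequencies(
    table: HaplotypeTable, locus: str, population: str
) -> AlleleFrequencySpectrum:
    """Empirical allele-frequency spectrum of ``population`` at ``locus``."""
    mask = table.population_mask(population)
    if not mask.any():
        raise ValidationError(f"population {population!r} is empty or unknown")
    calls = table.calls_at(locus).to_numpy()[mask]
    values = []
    for call in calls:
        if not call.is_integer:
            raise ValidationError(
                f"non-integer call at {locus} in population {population!r}; run QC first"
            )
        values.append(call.value)
    uniques, counts = np.unique(np.asarray(values), return_counts=True)
    n = len(values)
    freqs = {int(a): c / n for a, c in zip(uniques, counts)}
    return AlleleFrequencySpectrum(locus, population, freqs, n)


def afd(spec1: AlleleFrequencySpectrum, spec2: AlleleFrequencySpectrum) -> float:
    """AFD between two spectra: half the L1 distance over the allele union.

    Alleles absent from one population contribute frequency 0 there.
    Symmetric; bounded in [0, 1].
    """
    if spec1.locus != spec2.locus:
        raise ValidationError(f"locus mismatch: {spec1.locus} vs {spec2.locus}")
    alleles = set(spec1.freqs) | set(spec2.freqs)
    total = sum(abs(spec1.frequency(a) - spec2.frequency(a)) for a in alleles)
    return 0.5 * total


def mafd(table: HaplotypeTable, locus: str) -> tuple:
    """Mean AFD at ``locus`` over all unordered population pairs.

    Unweighted arithmetic mean; returns ``(mafd, n_pairs)``.
    """
    pops = table.populations
    if len(pops) < 2:
        raise ValidationError("mAFD needs at least two populations")
    spectra = {p: allele_frequencies(table, locus, p) for p in pops}
    pairs = list(combinations(pops, 2))
    value = float(np.mean([afd(spectra[a], spectra[b]) for a, b in pairs]))
    return value, len(pairs)


@dataclass
class MafdTable:
    """Per-locus mAFD values (descending), optionally with mutation rates.

    ``rows`` is a DataFrame with columns ``rank, locus, mafd, n_pairs,
    mutation_rate``; ties in mAFD are broken by locus name so rankings are
    deterministic across runs.
    """

    rows: pd.DataFrame
    populations_used: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rows["locus"].duplicated().any():
            raise ValidationError("duplicate loci in mAFD table")
        bad = self.rows[(self.rows["mafd"] < 0) | (self.rows["mafd"] > 1)]
        if len(bad):
            raise ValidationError(f"mAFD out of [0,1] at {bad['locus'].tolist()}")

    @property
    def ranking(self) -> list:
        """Locus names in descending mAFD order."""
        return self.rows["locus"].tolist()

    def value(self, locus: str) -> float:
        sel = self.rows.loc[self.rows["locus"] == locus, "mafd"]
        if sel.empty:
            raise ValidationError(f"locus {locus!r} not in mAFD table")
        return float(sel.iloc[0])

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_values(
        cls,
        values: Mapping,
        n_pairs: int,
        rates: Mapping | None = None,
        populations_used: Sequence | None = None,
    ) -> "MafdTable":
        items = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(items) + 1),
                "locus": [k for k, _ in items],
                "mafd": [v for _, v in items],
                "n_pairs": n_pairs,
                "mutation_rate": [
                    (rates or {}).get(k, np.nan) for k, _ in items
                ],
            }
        )
        return cls(df, list(populations_used or []))


def mafd_table(
    table: HaplotypeTable,
    panel: MarkerPanel,
    rates: Mapping | None = None,
) -> MafdTable:
    """mAFD for every panel locus, ranked descending (ties by locus name)."""
    values = {}
    n_pairs = 0
    for locus in panel:
        values[locus], n_pairs = mafd(table, locus)
    return MafdTable.from_values(values, n_pairs, rates, table.populations)


def load_reference_mafd() -> MafdTable:
    """The packaged 23-locus reference mAFD table (41-population compilation).

    Shipped as a versioned fixture; values are read from the data file,
    never hard-coded in logic.
    """
    ref = resources.files("ystrdiff.data") / "reference_mafd.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    rows = pd.DataFrame(
        {
            "rank": df["rank"],
            "locus": df["locus"],
            "mafd": df["mafd"],
            "n_pairs": 41 * 40 // 2,
            "mutation_rate": df["mutation_rate"],
        }
    )
    return MafdTable(rows)


@dataclass(frozen=True)
class SlidingPanelSeries:
    """Contiguous fixed-size windows over a descending mAFD ranking."""

    panels: tuple
    window: int
    step: int
    ranking: tuple

    def __len__(self) -> int:
        return len(self.panels)

    def __iter__(self):
        return iter(self.panels)

    @property
    def top(self) -> MarkerPanel:
        return self.panels[0]

    @property
    def minimum(self) -> MarkerPanel:
        return self.panels[-1]


def sliding_panels(ranking: MafdTable, window: int = 15, step: int = 1) -> SlidingPanelSeries:
    """Build marker panels by sliding a window down the mAFD ranking.

    The first panel holds the top-``window`` loci, the last the
    minimum-``window`` loci; 23 loci with window 15 and step 1 give 9 panels.
    """
    loci = ranking.ranking
    if window > len(loci):
        raise ValidationError(f"window {window} exceeds {len(loci)} ranked loci")
    if step < 1:
        raise ValidationError("step must be >= 1")
    panels = []
    for k in range(0, len(loci) - window + 1, step):
        panels.append(MarkerPanel(f"mafd_rank_{k + 1}_{k + window}", loci[k : k + window]))
    return SlidingPanelSeries(tuple(panels), window, step, tuple(loci))


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    degenerate: bool = False


def mafd_rate_correlation(mafd_tbl: MafdTable) -> CorrelationResult:
    """Pearson and Spearman correlation of mAFD with mutation rate.

    A zero-variance input (all rates equal, or all mAFD equal) makes the
    coefficients undefined; that case is reported as NaN with the
    ``degenerate`` flag set rather than raising.
    """
    rows = mafd_tbl.rows.dropna(subset=["mutation_rate"])
    if len(rows) < 3:
        raise ValidationError("need >= 3 loci with mutation rates for a correlation")
    x = rows["mafd"].to_numpy(float)
    y = rows["mutation_rate"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, len(rows), degenerate=True)
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(
        float(pr.statistic), float(pr.pvalue), float(sr.statistic), float(sr.pvalue), len(rows)
    )
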