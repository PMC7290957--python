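"""Synthetic multi-population Y-STR haplotype generator.

The simulator emulates the kind of data the pipeline is built for: many
male populations typed at single-copy Y-STR loci, with population-specific
allele spectra shaped by founder events and genetic drift.  It is a forward
Wright-Fisher simulation of haploid haplotypes: one ancestral pool with
standing variation, a star split into daughter populations through founder
bottlenecks, then per-generation resampling with a strict stepwise mutation
model (repeat count +-1 with equal probability, reflecting at a lower bound
of one repeat) at per-locus rates on the order of real Y-STR rates
(1e-4 to 1e-2 per generation).

Optionally, QC artifacts (null, intermediate, duplicated calls) are
injected at configurable rates so the QC stage can be exercised end to end.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .frequency_afd import AlleleFrequencySpectrum, load_reference_mafd
from .iohap import AlleleCall, HaplotypeTable

_OFFSETS = np.array([-2, -1, 0, 1, 2])


def default_mutation_rates() -> dict:
    """Per-locus rates for the 23-locus reference panel (packaged fixture)."""
    ref = load_reference_mafd()
    return {
        locus: float(rate)
        for locus, rate in zip(ref.rows["locus"], ref.rows["mutation_rate"])
    }


@dataclass
class SimulationConfig:
    """Knobs of the forward simulation.

    Defaults mirror the scale of the compiled study data (41 populations,
    roughly 510 haplotypes each, the 23-locus reference panel with its
    published mutation rates); founder size, split age and ancestral
    diversity are free parameters with field-plausible defaults.
    """

    n_populations: int = 41
    pop_size: int = 510
    founder_size: int = 50
    generations_since_split: int | Sequence = 300
    mutation_rates: Mapping | None = None  # default: reference panel rates
    qc_noise: Mapping = field(default_factory=dict)  # {null|intermediate|duplicated: rate}
    seed: int = 0
    ancestral_pool_size: int = 1000
    ancestral_diversity: float = 0.5  # 0 => monomorphic ancestral pool
    topology: str = "star"

    def __post_init__(self) -> None:
        if min(self.n_populations, self.pop_size, self.founder_size) < 1:
            raise ValidationError("population counts and sizes must be >= 1")
        if self.mutation_rates is None:
            self.mutation_rates = default_mutation_rates()
        if not self.mutation_rates:
            raise ValidationError("locus list is empty")
        for locus, rate in self.mutation_rates.items():
            if not (0.0 <= rate < 1.0):
                raise ValidationError(f"mutation rate for {locus} must lie in [0, 1)")
        for reason, rate in self.qc_noise.items():
            if reason not in ("null", "intermediate", "duplicated"):
                raise ValidationError(f"unknown QC-noise class {reason!r}")
            if not (0.0 <= rate < 1.0):
                raise ValidationError("QC-noise rates must lie in [0, 1)")
        if not (0.0 <= self.ancestral_diversity <= 0.6):
            raise ValidationError("ancestral_diversity must lie in [0, 0.6]")
        if self.topology not in ("star", "balanced"):
            raise ValidationError("topology must be 'star' or 'balanced'")
        if self.topology == "balanced" and not isinstance(
            self.generations_since_split, (int, np.integer)
        ):
            raise ValidationError("balanced topology takes a single root-to-leaf split age")

    @property
    def loci(self) -> list:
        return list(self.mutation_rates)

    def generations(self) -> list:
        g = self.generations_since_split
        if isinstance(g, (int, np.integer)):
            gens = [int(g)] * self.n_populations
        else:
            gens = [int(v) for v in g]
        if len(gens) != self.n_populations:
            raise ValidationError("need one generations value per population")
        if any(v < 0 for v in gens):
            raise ValidationError("generations must be >= 0")
        return gens


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated table."""

    ancestral_haplotype: dict
    split_topology: str
    realized_mutation_counts: dict

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "ancestral_haplotype": self.ancestral_haplotype,
                    "split_topology": self.split_topology,
                    "realized_mutation_counts": self.realized_mutation_counts,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def _mutate(pop: np.ndarray, rates: np.ndarray, rng: np.random.Generator) -> int:
    """Apply one generation of stepwise mutation in place; returns hit count."""
    mask = rng.random(pop.shape) < rates[None, :]
    n_hits = int(mask.sum())
    if n_hits:
        steps = rng.integers(0, 2, size=n_hits) * 2 - 1
        pop[mask] += steps
        # reflect at the lower physical bound of one repeat
        low = pop < 1
        pop[low] = 2 - pop[low]
    return n_hits


def simulate_populations(config: SimulationConfig) -> tuple:
    """Run the forward simulation; returns (HaplotypeTable, TruthRecord).

    Each daughter population starts from ``founder_size`` haplotypes drawn
    from the ancestral pool, expands to ``pop_size`` in the first
    post-split generation, and then drifts under Wright-Fisher resampling
    with stepwise mutation.  A split age of zero bypasses the bottleneck:
    the population is a plain resample of the ancestral pool.
    """
    rng_root = np.random.SeedSequence(int(config.seed) & 0x7FFFFFFF)
    # fixed spawn order: ancestral pool, then one stream per population, then noise
    streams = rng_root.spawn(config.n_populations + 2)
    rng_anc = np.random.default_rng(streams[0])

    loci = config.loci
    rates = np.array([config.mutation_rates[l] for l in loci], float)
    n_loci = len(loci)

    # ancestral pool at mutation-drift "equilibrium" stand-in: a modal repeat
    # per locus plus small symmetric offsets controlled by ancestral_diversity
    modal = rng_anc.integers(10, 25, size=n_loci)
    # DYS389II physically contains DYS389I, so its total repeat count sits
    # well above DYS389I; keep the nested structure in the ancestral pool
    if "DYS389I" in loci and "DYS389II" in loci:
        i1, i2 = loci.index("DYS389I"), loci.index("DYS389II")
        modal[i2] = modal[i1] + int(rng_anc.integers(14, 19))
    d = config.ancestral_diversity
    probs = np.array([d / 4, d / 2, 1 - 1.5 * d, d / 2, d / 4])
    offsets = rng_anc.choice(_OFFSETS, size=(config.ancestral_pool_size, n_loci), p=probs)
    ancestral = modal[None, :] + offsets

    generations = config.generations()
    if config.topology == "star":
        blocks, mutation_counts = _simulate_star(ancestral, generations, config, rates, streams)
    else:
        rng = np.random.default_rng(streams[1])
        blocks, mutation_counts = _simulate_balanced(
            ancestral, generations[0], config, rates, rng
        )
    sample_ids, pops_col = [], []
    for k in range(config.n_populations):
        pop_id = f"pop{k + 1:02d}"
        pops_col.extend([pop_id] * config.pop_size)
        sample_ids.extend(f"{pop_id}_s{i + 1:05d}" for i in range(config.pop_size))

    alleles = np.vstack(blocks)
    table = HaplotypeTable.from_numeric(sample_ids, pops_col, loci, alleles)
    if config.qc_noise:
        table = inject_qc_noise(
            table, config.qc_noise, seed=None, _seed_sequence=streams[-1]
        )
    truth = TruthRecord(
        ancestral_haplotype={l: int(m) for l, m in zip(loci, modal)},
        split_topology=config.topology,
        realized_mutation_counts=mutation_counts,
    )
    return table, truth


def _evolve_branch(
    pool: np.ndarray,
    gens: int,
    out_size: int,
    founder_size: int,
    rates: np.ndarray,
    rng: np.random.Generator,
) -> tuple:
    """One branch: founder bottleneck, expansion to ``out_size``, WF drift.

    Returns the final generation and the realized mutation count.
    A branch of zero generations is a plain resample (no bottleneck).
    """
    realized = 0
    if gens == 0:
        return pool[rng.integers(0, len(pool), size=out_size)].copy(), 0
    current = pool[rng.integers(0, len(pool), size=founder_size)]
    for _ in range(gens):
        current = current[rng.integers(0, len(current), size=out_size)].copy()
        realized += _mutate(current, rates, rng)
    return current, realized


def _simulate_star(ancestral, generations, config, rates, streams) -> tuple:
    blocks, counts = [], {}
    for k in range(config.n_populations):
        rng = np.random.default_rng(streams[k + 1])
        block, realized = _evolve_branch(
            ancestral, generations[k], config.pop_size, config.founder_size, rates, rng
        )
        blocks.append(block)
        counts[f"pop{k + 1:02d}"] = realized
    return blocks, counts


def _simulate_balanced(ancestral, total_gens, config, rates, rng) -> tuple:
    """Balanced binary splits; each branch consumes an equal share of the
    root-to-leaf split age, so sister populations are nested more closely
    than distant ones."""
    import math

    n_pops = config.n_populations
    depth = max(1, math.ceil(math.log2(n_pops))) if n_pops > 1 else 1
    g_branch = total_gens // depth
    blocks, counts = [], {}

    def recurse(pool: np.ndarray, k: int, inherited: int) -> None:
        if k == 1:
            block, realized = _evolve_branch(
                pool, g_branch, config.pop_size, config.founder_size, rates, rng
            )
            pop_id = f"pop{len(blocks) + 1:02d}"
            blocks.append(block)
            counts[pop_id] = inherited + realized
            return
        for child_k in ((k + 1) // 2, k // 2):
            child_pool, realized = _evolve_branch(
                pool, g_branch, config.pop_size, config.founder_size, rates, rng
            )
            recurse(child_pool, child_k, inherited + realized)

    recurse(ancestral, n_pops, 0)
    return blocks, counts


def sample_from_spectra(
    spectra: Iterable[AlleleFrequencySpectrum], n: int, seed: int = 0
) -> HaplotypeTable:
    """Draw ``n`` haplotypes per population from prescribed allele spectra.

    Loci are sampled independently; every population must provide a
    normalized spectrum for the same locus set.  Empirical frequencies
    converge to the inputs as ``n`` grows.
    """
    by_pop: dict = {}
    for spec in spectra:
        total = float(sum(spec.freqs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"spectrum {spec.locus}/{spec.population} is not normalized (sum={total})"
            )
        by_pop.setdefault(spec.population, {})[spec.locus] = spec
    if not by_pop:
        raise ValidationError("no spectra given")
    loci_sets = {pop: tuple(sorted(d)) for pop, d in by_pop.items()}
    if len(set(loci_sets.values())) != 1:
        raise ValidationError("populations cover different locus sets")
    loci = list(next(iter(loci_sets.values())))

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    sample_ids, pops_col, rows = [], [], []
    for pop in sorted(by_pop):
        cols = []
        for locus in loci:
            spec = by_pop[pop][locus]
            alleles = np.array(sorted(spec.freqs), dtype=np.int64)
            p = np.array([spec.freqs[a] for a in alleles], float)
            p = p / p.sum()  # remove rounding slack
            cols.append(rng.choice(alleles, size=n, p=p))
        rows.append(np.column_stack(cols))
        pops_col.extend([pop] * n)
        sample_ids.extend(f"{pop}_s{i + 1:05d}" for i in range(n))
    return HaplotypeTable.from_numeric(sample_ids, pops_col, loci, np.vstack(rows))


def inject_qc_noise(
    table: HaplotypeTable,
    rates: Mapping,
    seed: int | None = 0,
    _seed_sequence: np.random.SeedSequence | None = None,
) -> HaplotypeTable:
    """Corrupt randomly chosen records with null/intermediate/duplicated calls.

    Each record is hit by each artifact class independently with the given
    per-class probability, at one randomly chosen single-copy locus, so
    expected counts are rate * n per class.  Returns a new table.
    """
    for reason, rate in rates.items():
        if reason not in ("null", "intermediate", "duplicated"):
            raise ValidationError(f"unknown QC-noise class {reason!r}")
        if not (0.0 <= rate < 1.0):
            raise ValidationError("QC-noise rates must lie in [0, 1)")
    if _seed_sequence is None:
        _seed_sequence = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    rng = np.random.default_rng(_seed_sequence)
    data = table.data.copy()
    single_loci = [l.name for l in table.loci if l.copy_class == "single"]
    if not single_loci:
        raise ValidationError("table has no single-copy loci to corrupt")
    n = len(data)
    for reason in ("null", "intermediate", "duplicated"):  # fixed draw order
        rate = rates.get(reason, 0.0)
        if rate == 0.0:
            continue
        hit = rng.random(n) < rate
        locus_idx = rng.integers(0, len(single_loci), size=n)
        for i in np.flatnonzero(hit):
            locus = single_loci[locus_idx[i]]
            old = data.iloc[i, data.columns.get_loc(locus)]
            base = old.value if old.is_integer else 10
            if reason == "null":
                new = AlleleCall.null()
            elif reason == "intermediate":
                new = AlleleCall("intermediate", base + 0.2)
            else:
                new = AlleleCall("multi", (base, base + 1))
            data.iloc[i, data.columns.get_loc(locus)] = new
    return HaplotypeTable(data, table.loci, table.dys389_adjusted)
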