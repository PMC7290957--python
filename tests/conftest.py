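"""Shared fixtures: tiny hand-built haplotype tables and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from ystrdiff.iohap import AlleleCall, HaplotypeTable, MarkerPanel


def make_table(alleles_by_population: dict, locus_names: list) -> HaplotypeTable:
    """Build a clean integer table from {population: (n, L) array-like}."""
    sample_ids, pops, blocks = [], [], []
    counter = 0
    for pop, mat in alleles_by_population.items():
        mat = np.asarray(mat)
        for _ in range(mat.shape[0]):
            counter += 1
            sample_ids.append(f"s{counter:04d}")
            pops.append(pop)
        blocks.append(mat)
    return HaplotypeTable.from_numeric(sample_ids, pops, locus_names, np.vstack(blocks))


@pytest.fixture
def two_locus_table() -> HaplotypeTable:
    """Two populations, two loci, hand-countable spectra."""
    return make_table(
        {
            "A": [[13, 20], [13, 21], [14, 20], [15, 20]],
            "B": [[14, 22], [14, 22], [14, 21], [13, 22]],
        },
        ["DYS392", "DYS391"],
    )


@pytest.fixture
def messy_records():
    """Five haplotypes: clean, null, intermediate, multi, and null+multi."""
    L = ["DYS392", "DYS448"]

    def row(a, b):
        return {"DYS392": a, "DYS448": b}

    ok = AlleleCall("integer", 13)
    return (
        [
            ("s1", "A", row(ok, AlleleCall("integer", 20))),
            ("s2", "A", row(ok, AlleleCall.null())),
            ("s3", "A", row(AlleleCall("intermediate", 13.2), AlleleCall("integer", 20))),
            ("s4", "B", row(ok, AlleleCall("multi", (17, 18)))),
            ("s5", "B", row(AlleleCall.null(), AlleleCall("multi", (17, 18)))),
        ],
        L,
    )


@pytest.fixture
def messy_table(messy_records) -> HaplotypeTable:
    records, loci = messy_records
    return HaplotypeTable.from_records(records, loci)


@pytest.fixture
def panel_two() -> MarkerPanel:
    return MarkerPanel("two", ["DYS392", "DYS448"])
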