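"""Reading, validation and QC of Y-STR haplotype tables.

A haplotype table holds one row per male sample (sample id, population id,
one allele call per locus).  Allele calls at a single-copy Y-STR are repeat
counts; real genotyping output also contains null alleles (no amplification),
intermediate alleles (microvariants such as 13.2), and duplicated or
triplicated alleles (multi-value calls at a nominally single-copy locus).
QC removes any haplotype carrying one of those states at a panel locus,
whole-haplotype, so downstream statistics see clean integer repeat counts.

DYS389II amplicons physically contain DYS389I, so the independent component
of DYS389II is DYS389II - DYS389I; :func:`adjust_dys389` applies that
decomposition once per table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: cell tokens interpreted as a null (dropped-out) allele
NULL_SENTINELS = frozenset({"", "NA", "na", "null", "-", "nan"})

#: columns that are metadata, never loci
RESERVED_COLUMNS = ("sample", "population")


# ---------------------------------------------------------------------------
# allele calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleCall:
    """One allele call at one locus: exactly one of four states.

    ``kind`` is one of ``integer`` (clean repeat count >= 1),
    ``intermediate`` (non-integer microvariant, e.g. 13.2), ``null``
    (no amplification), or ``multi`` (duplicated/triplicated call,
    stored as a sorted tuple of values).
    """

    kind: str
    value: int | float | tuple | None = None

    _KINDS = ("integer", "intermediate", "null", "multi")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValidationError(f"unknown allele-call kind {self.kind!r}")
        if self.kind == "integer" and (not isinstance(self.value, int) or self.value < 1):
            raise ValidationError(f"integer allele must be an int >= 1, got {self.value!r}")
        if self.kind == "null" and self.value is not None:
            raise ValidationError("null allele carries no value")

    @property
    def is_integer(self) -> bool:
        return self.kind == "integer"

    @classmethod
    def null(cls) -> "AlleleCall":
        return cls("null")

    @classmethod
    def parse(cls, token: object, null_sentinels: frozenset = NULL_SENTINELS) -> "AlleleCall":
        """Parse one table cell into an allele call.

        Unparseable tokens become null calls with a logged warning rather
        than aborting the read.
        """
        if token is None or (isinstance(token, float) and np.isnan(token)):
            return cls.null()
        if isinstance(token, (int, np.integer)):
            return cls("integer", int(token))
        if isinstance(token, float):
            return cls._from_number(float(token))
        text = str(token).strip()
        if text in null_sentinels:
            return cls.null()
        if "," in text or "/" in text:
            sep = "," if "," in text else "/"
            try:
                values = tuple(sorted(
                    int(v) if v.is_integer() else v
                    for v in (cls._parse_number(p) for p in text.split(sep))
                ))
            except ValueError:
                logger.warning("unparseable multi-allele cell %r treated as null", text)
                return cls.null()
            return cls("multi", values)
        try:
            return cls._from_number(cls._parse_number(text))
        except (ValueError, ValidationError):
            logger.warning("unparseable allele cell %r treated as null", text)
            return cls.null()

    @staticmethod
    def _parse_number(text: str) -> float:
        return float(text.strip())

    @classmethod
    def _from_number(cls, x: float) -> "AlleleCall":
        if float(x).is_integer():
            return cls("integer", int(x))
        return cls("intermediate", float(x))

    def __str__(self) -> str:
        if self.kind == "null":
            return ""
        if self.kind == "multi":
            return ",".join(str(v) for v in self.value)
        return str(self.value)


# ---------------------------------------------------------------------------
# loci and panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """A Y-STR locus: name, copy class, optional per-generation mutation rate."""

    name: str
    copy_class: str = "single"  # {"single", "multi"}
    mutation_rate: float | None = None
    in_yfiler: bool = False

    def __post_init__(self) -> None:
        if self.copy_class not in ("single", "multi"):
            raise ValidationError(f"copy_class must be single|multi, got {self.copy_class!r}")
        if self.mutation_rate is not None and not (0.0 < self.mutation_rate < 1.0):
            raise ValidationError(f"mutation_rate must lie in (0, 1), got {self.mutation_rate}")


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered, duplicate-free list of locus names under a panel name."""

    name: str
    loci: tuple

    def __init__(self, name: str, loci: Iterable[str]):
        loci = tuple(loci)
        if len(set(loci)) != len(loci):
            raise ValidationError(f"panel {name!r} contains duplicate loci")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "loci", loci)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __contains__(self, locus: str) -> bool:
        return locus in self.loci

    def write(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{l}\n" for l in self.loci))

    @classmethod
    def read(cls, path: str | Path, name: str | None = None) -> "MarkerPanel":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        return cls(name or Path(path).stem, [ln for ln in lines if ln and not ln.startswith("#")])


# the 23 single-copy loci of the extended (Plus) panel, in kit order;
# the second element flags membership in the original 17-locus kit
_SINGLE_COPY_LOCI = (
    ("DYS19", True), ("DYS389I", True), ("DYS389II", True), ("DYS390", True),
    ("DYS391", True), ("DYS392", True), ("DYS393", True), ("DYS437", True),
    ("DYS438", True), ("DYS439", True), ("DYS448", True), ("DYS456", True),
    ("DYS458", True), ("DYS635", True), ("YGATAH4", True),
    ("DYS449", False), ("DYS460", False), ("DYS481", False), ("DYS518", False),
    ("DYS533", False), ("DYS570", False), ("DYS576", False), ("DYS627", False),
)

_MULTI_COPY_YFILER = ("DYS385a", "DYS385b")
_MULTI_COPY_PLUS = ("DYF387S1a", "DYF387S1b")

#: names of multi-copy loci ignored by single-copy analyses
MULTI_COPY_LOCI = frozenset(_MULTI_COPY_YFILER + _MULTI_COPY_PLUS)


def builtin_panels() -> dict:
    """Built-in marker panels.

    ``yfiler``: the 17-locus kit (15 single-copy loci plus DYS385a/b).
    ``yfiler_plus``: the 27-locus kit (23 single-copy plus the two
    multi-copy pairs).  ``single_copy_23``: the 23 single-copy loci of the
    extended kit, the panel every frequency-based statistic here runs on.
    """
    single = [n for n, _ in _SINGLE_COPY_LOCI]
    yfiler_single = [n for n, in_y in _SINGLE_COPY_LOCI if in_y]
    return {
        "yfiler": MarkerPanel("yfiler", yfiler_single + list(_MULTI_COPY_YFILER)),
        "yfiler_plus": MarkerPanel(
            "yfiler_plus", single + list(_MULTI_COPY_YFILER) + list(_MULTI_COPY_PLUS)
        ),
        "single_copy_23": MarkerPanel("single_copy_23", single),
    }


# ---------------------------------------------------------------------------
# haplotype tables
# ---------------------------------------------------------------------------

class HaplotypeTable:
    """Per-sample, per-locus allele calls grouped by population.

    Internally a pandas DataFrame indexed by sample id, with a
    ``population`` column and one object-dtype column of
    :class:`AlleleCall` per locus.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        loci: Sequence[Locus] | None = None,
        dys389_adjusted: bool = False,
    ):
        if "population" not in data.columns:
            raise ValidationError("table needs a 'population' column")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        locus_names = [c for c in data.columns if c != "population"]
        if loci is None:
            loci = [
                Locus(n, "multi" if n in MULTI_COPY_LOCI else "single") for n in locus_names
            ]
        if [l.name for l in loci] != locus_names:
            raise ValidationError("locus metadata does not match table columns")
        if len(data) and data["population"].nunique() < 1:
            raise ValidationError("table must contain at least one population")
        self.data = data
        self.loci = list(loci)
        self.dys389_adjusted = dys389_adjusted

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        locus_names: Sequence[str],
        dys389_adjusted: bool = False,
    ) -> "HaplotypeTable":
        """Build from (sample_id, population_id, {locus: AlleleCall}) triples."""
        rows, index = [], []
        for sample_id, pop, calls in records:
            missing = set(locus_names) - set(calls)
            if missing:
                raise ValidationError(f"sample {sample_id!r} lacks calls for {sorted(missing)}")
            index.append(str(sample_id))
            rows.append([pop] + [calls[l] for l in locus_names])
        df = pd.DataFrame(rows, columns=["population", *locus_names], index=index)
        return cls(df, dys389_adjusted=dys389_adjusted)

    @classmethod
    def from_numeric(
        cls,
        sample_ids: Sequence[str],
        populations: Sequence[str],
        locus_names: Sequence[str],
        alleles: np.ndarray,
        dys389_adjusted: bool = False,
    ) -> "HaplotypeTable":
        """Fast path from an integer allele matrix (n_samples x n_loci)."""
        alleles = np.asarray(alleles)
        calls = {
            locus: [AlleleCall("integer", int(v)) for v in alleles[:, j]]
            for j, locus in enumerate(locus_names)
        }
        df = pd.DataFrame({"population": list(populations), **calls},
                          index=[str(s) for s in sample_ids])
        return cls(df, dys389_adjusted=dys389_adjusted)

    # -- basic views --------------------------------------------------------

    @property
    def locus_names(self) -> list:
        return [l.name for l in self.loci]

    @property
    def populations(self) -> list:
        """Population ids in order of first appearance."""
        return list(dict.fromkeys(self.data["population"]))

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def population_mask(self, population: str) -> np.ndarray:
        return (self.data["population"] == population).to_numpy()

    def subset(self, mask: np.ndarray) -> "HaplotypeTable":
        return HaplotypeTable(self.data.loc[mask].copy(), self.loci, self.dys389_adjusted)

    def calls_at(self, locus: str) -> pd.Series:
        if locus not in self.data.columns:
            raise ValidationError(f"locus {locus!r} not in table")
        return self.data[locus]

    def numeric_matrix(self, loci: Sequence[str] | None = None) -> np.ndarray:
        """Integer allele matrix over ``loci`` (default: all single-copy loci).

        Requires every requested call to be a clean integer, i.e. a QC'd
        table; raises otherwise.
        """
        loci = list(loci) if loci is not None else [
            l.name for l in self.loci if l.copy_class == "single"
        ]
        out = np.empty((len(self.data), len(loci)), dtype=np.int64)
        for j, locus in enumerate(loci):
            col = self.calls_at(locus)
            for i, call in enumerate(col.to_numpy()):
                if not call.is_integer:
                    raise ValidationError(
                        f"non-integer call at {locus} for sample {col.index[i]!r}; run QC first"
                    )
                out[i, j] = call.value
        return out

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        out = self.data.copy()
        for locus in self.locus_names:
            out[locus] = out[locus].map(str)
        out.insert(0, "sample", out.index)
        out.to_csv(path, sep=sep, index=False)


def read_haplotype_table(path: str | Path, dialect: str | None = None) -> HaplotypeTable:
    """Read a delimited haplotype table (TSV default, CSV accepted).

    The header must name ``sample`` and ``population`` columns; every other
    column is a locus.  Unparseable cells become null calls with a warning.
    """
    path = Path(path)
    if dialect is None:
        dialect = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        raw = pd.read_csv(path, sep=dialect, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in RESERVED_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: header lacks required column(s) {missing}")
    if raw["sample"].duplicated().any():
        dupes = raw.loc[raw["sample"].duplicated(), "sample"].tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dupes[:5]}")
    locus_names = [c for c in raw.columns if c not in RESERVED_COLUMNS]
    parsed = {"population": raw["population"].to_numpy()}
    for locus in locus_names:
        parsed[locus] = [AlleleCall.parse(v) for v in raw[locus]]
    df = pd.DataFrame(parsed, index=raw["sample"].to_numpy())
    return HaplotypeTable(df)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

#: removal-reason precedence, fixed for reproducible reports
QC_REASONS = ("null", "intermediate", "multi_allele")

_KIND_TO_REASON = {"null": "null", "intermediate": "intermediate", "multi": "multi_allele"}


@dataclass
class QcReport:
    """Bookkeeping for a QC pass: counts reconcile exactly.

    A haplotype removable for several reasons is counted once, under the
    first applicable reason in the order null -> intermediate -> multi_allele.
    """

    n_input: int
    n_retained: int
    removed_by_reason: dict
    dys389_adjusted: bool = False
    removed_by_population: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + sum(self.removed_by_reason.values()):
            raise ValidationError("QC counts do not reconcile")

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "removed_by_reason": self.removed_by_reason,
                "removed_by_population": self.removed_by_population,
                "dys389_adjusted": self.dys389_adjusted,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def qc_filter(table: HaplotypeTable, panel: MarkerPanel) -> tuple:
    """Remove whole haplotypes with null/intermediate/multi calls at panel loci.

    Returns the filtered table and a :class:`QcReport`.  Multi-copy loci in
    the panel are skipped: a duplicated call is the expected state there,
    not an artifact.
    """
    if len(panel) == 0:
        raise ValidationError("QC panel is empty")
    missing = [l for l in panel if l not in table.data.columns]
    if missing:
        raise ValidationError(f"panel loci absent from table: {missing}")
    check_loci = [l for l in panel if l not in MULTI_COPY_LOCI]

    reasons = np.full(table.n_samples, "", dtype=object)
    for locus in check_loci:
        kinds = np.array([c.kind for c in table.calls_at(locus)], dtype=object)
        for kind in ("null", "intermediate", "multi"):  # precedence order
            hit = (kinds == kind) & (reasons == "")
            reasons[hit] = _KIND_TO_REASON[kind]
    # precedence must hold across loci too: re-scan flagged rows for an
    # earlier-precedence state at any checked locus
    flagged = np.flatnonzero(reasons != "")
    for i in flagged:
        kinds_i = {table.data.iloc[i][l].kind for l in check_loci}
        for kind in ("null", "intermediate", "multi"):
            if kind in kinds_i:
                reasons[i] = _KIND_TO_REASON[kind]
                break

    keep = reasons == ""
    removed_by_reason = {r: int((reasons == r).sum()) for r in QC_REASONS}
    pops = table.data["population"].to_numpy()
    removed_by_population = {}
    for pop in table.populations:
        pop_mask = pops == pop
        removed_by_population[pop] = {
            r: int(((reasons == r) & pop_mask).sum()) for r in QC_REASONS
        }
    report = QcReport(
        n_input=table.n_samples,
        n_retained=int(keep.sum()),
        removed_by_reason=removed_by_reason,
        dys389_adjusted=table.dys389_adjusted,
        removed_by_population=removed_by_population,
    )
    return table.subset(keep), report


def adjust_dys389(table: HaplotypeTable) -> HaplotypeTable:
    """Replace DYS389II by DYS389II - DYS389I (the non-nested amplicon part).

    Refuses to run twice (tracked by a table-level flag) and requires clean
    integer calls at both loci, i.e. a QC'd table.
    """
    if table.dys389_adjusted:
        raise ValidationError("table is already DYS389-adjusted")
    for locus in ("DYS389I", "DYS389II"):
        if locus not in table.data.columns:
            raise ValidationError(f"{locus} missing; cannot adjust DYS389")
    data = table.data.copy()
    adjusted = []
    for sample_id, row in data.iterrows():
        a, b = row["DYS389I"], row["DYS389II"]
        if not (a.is_integer and b.is_integer):
            raise ValidationError(f"sample {sample_id!r}: DYS389 calls not integer; run QC first")
        diff = b.value - a.value
        if diff <= 0:
            raise ValidationError(
                f"sample {sample_id!r}: DYS389II ({b.value}) - DYS389I ({a.value}) = {diff} <= 0"
            )
        adjusted.append(AlleleCall("integer", diff))
    data["DYS389II"] = adjusted
    return HaplotypeTable(data, table.loci, dys389_adjusted=True)
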