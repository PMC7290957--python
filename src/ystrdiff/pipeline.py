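"""End-to-end orchestration: ingest -> QC -> mAFD -> panels -> distances -> MDS.

One call (:func:`run_characterization`) reproduces the full locus-
characterization workflow on either a real haplotype table or a simulated
one: QC filtering, the DYS389 decomposition, per-locus mAFD ranking,
sliding 15-marker panels, AMOVA distance matrices with permutation
p-values for the top and minimum panels (optionally also for the
17-vs-27-locus kit comparison), pair-by-pair matrix comparisons, and MDS
embeddings.  All outputs are plain text (TSV/JSON/PHYLIP) and byte-stable
under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .errors import ValidationError
from .frequency_afd import (
    CorrelationResult,
    MafdTable,
    load_reference_mafd,
    mafd_rate_correlation,
    mafd_table,
    sliding_panels,
)
from .gendist import (
    MatrixComparison,
    PairwiseDistanceMatrix,
    compare_distance_matrices,
    distance_matrix,
)
from .iohap import (
    MULTI_COPY_LOCI,
    HaplotypeTable,
    MarkerPanel,
    QcReport,
    adjust_dys389,
    builtin_panels,
    qc_filter,
    read_haplotype_table,
)
from .mds import MdsEmbedding, classical_mds, smacof_refine
from .synthetic_data import SimulationConfig, simulate_populations

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one characterization run.

    Defaults match the reference analysis settings: 10,000 permutations,
    significance level 0.05, 15-marker windows with step 1, 2-D MDS.
    ``fast`` lowers the permutation count to 500 for quick turnaround.
    """

    input_path: str | None = None
    simulation: SimulationConfig | None = None
    n_perm: int = 10_000
    alpha: float = 0.05
    window: int = 15
    step: int = 1
    metric: str = "sum_squared_size_diff"
    mds_method: str = "classical"
    clamp_negative: bool = True
    compare_kits: bool = True
    seed: int = 0
    outdir: str | None = None
    fast: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValidationError("give exactly one of input_path or simulation")
        if self.mds_method not in ("classical", "smacof"):
            raise ValidationError("mds_method must be classical|smacof")
        if self.fast:
            self.n_perm = min(self.n_perm, 500)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance."""
        payload = {
            k: v for k, v in vars(self).items() if k not in ("simulation", "outdir")
        }
        if self.simulation is not None:
            payload["simulation"] = {
                k: (dict(v) if isinstance(v, Mapping) else v)
                for k, v in vars(self.simulation).items()
            }
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one run produced, traceable to the config hash."""

    config_hash: str
    seed: int
    qc: QcReport
    mafd: MafdTable
    panels: list
    distances: dict  # panel name -> PairwiseDistanceMatrix
    comparisons: dict  # label -> MatrixComparison
    embeddings: dict  # panel name -> MdsEmbedding
    correlation: CorrelationResult | None = None
    version: str = ""

    def write(self, outdir: str | Path) -> None:
        """Write every artifact as plain text under ``outdir``."""
        out = Path(outdir)
        for sub in ("panels", "distances", "comparisons", "mds"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        self.qc.to_json(out / "qc_report.json")
        self.mafd.to_tsv(out / "mafd_table.tsv")
        for panel in self.panels:
            panel.write(out / "panels" / f"{panel.name}.txt")
        for name, dm in self.distances.items():
            dm.to_tsv(out / "distances" / f"{name}.tsv")
            dm.to_phylip(out / "distances" / f"{name}.phylip")
        for label, cmp_ in self.comparisons.items():
            cmp_.to_tsv(out / "comparisons" / f"{label}.tsv")
            cmp_.to_json(out / "comparisons" / f"{label}.json")
        for name, emb in self.embeddings.items():
            emb.to_tsv(out / "mds" / f"{name}.tsv")
            (out / "mds" / f"{name}.json").write_text(
                json.dumps(
                    {"method": emb.method, "stress1": emb.stress, "panel": name},
                    indent=2,
                    sort_keys=True,
                )
                + "\n"
            )
        provenance = {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "correlation": None
            if self.correlation is None
            else {
                "pearson_r": self.correlation.pearson_r,
                "pearson_p": self.correlation.pearson_p,
                "spearman_rho": self.correlation.spearman_rho,
                "spearman_p": self.correlation.spearman_p,
                "degenerate": self.correlation.degenerate,
            },
        }
        (out / "run.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")


def _analysis_panel(table: HaplotypeTable) -> MarkerPanel:
    """All single-copy loci present in the table, in table order."""
    loci = [l.name for l in table.loci if l.copy_class == "single"]
    if not loci:
        raise ValidationError("table has no single-copy loci")
    return MarkerPanel("single_copy", loci)


def run_characterization(config: RunConfig) -> RunReport:
    """Execute the full pipeline and return (and optionally write) a report."""
    # -- ingest -------------------------------------------------------------
    if config.input_path is not None:
        logger.info("reading haplotype table from %s", config.input_path)
        table = read_haplotype_table(config.input_path)
    else:
        logger.info("simulating haplotype table (seed=%d)", config.simulation.seed)
        table, _truth = simulate_populations(config.simulation)

    # -- QC and DYS389 decomposition ---------------------------------------
    full_panel = MarkerPanel("all_loci", table.locus_names)
    table, qc_report = qc_filter(table, full_panel)
    logger.info("QC: retained %d of %d haplotypes", qc_report.n_retained, qc_report.n_input)
    names = set(table.locus_names)
    if {"DYS389I", "DYS389II"} <= names and not table.dys389_adjusted:
        table = adjust_dys389(table)
        qc_report.dys389_adjusted = True

    # -- mAFD ranking -------------------------------------------------------
    panel = _analysis_panel(table)
    reference = load_reference_mafd()
    rates = {
        locus: rate
        for locus, rate in zip(reference.rows["locus"], reference.rows["mutation_rate"])
        if locus in panel
    }
    mafd_tbl = mafd_table(table, panel, rates)
    correlation = None
    if mafd_tbl.rows["mutation_rate"].notna().sum() >= 3:
        correlation = mafd_rate_correlation(mafd_tbl)

    # -- sliding panels -----------------------------------------------------
    window = min(config.window, len(panel))
    series = sliding_panels(mafd_tbl, window=window, step=config.step)
    logger.info("built %d sliding panels (window %d)", len(series), window)

    # -- distance matrices, comparisons, MDS -------------------------------
    targets = {"top_panel": series.top}
    if len(series) > 1:
        targets["minimum_panel"] = series.minimum
    if config.compare_kits:
        yfiler_single = [
            l for l in builtin_panels()["yfiler"] if l in panel and l not in MULTI_COPY_LOCI
        ]
        if len(yfiler_single) >= 2 and len(yfiler_single) < len(panel):
            targets["yfiler_core"] = MarkerPanel("yfiler_core", yfiler_single)
            targets["full_core"] = panel

    distances = {}
    for name, target_panel in targets.items():
        named = MarkerPanel(name, list(target_panel))
        distances[name] = distance_matrix(
            table, named, n_perm=config.n_perm, seed=config.seed, metric=config.metric
        )

    comparisons = {}
    if "minimum_panel" in distances:
        comparisons["top_vs_minimum"] = compare_distance_matrices(
            distances["minimum_panel"], distances["top_panel"]
        )
    if "yfiler_core" in distances and "full_core" in distances:
        comparisons["full_vs_yfiler"] = compare_distance_matrices(
            distances["yfiler_core"], distances["full_core"]
        )

    embeddings = {}
    for name, dm in distances.items():
        emb = classical_mds(dm, dims=2, clamp_negative=config.clamp_negative)
        if config.mds_method == "smacof":
            emb = smacof_refine(emb, dm, clamp_negative=config.clamp_negative)
        embeddings[name] = emb

    report = RunReport(
        config_hash=config.digest(),
        seed=config.seed,
        qc=qc_report,
        mafd=mafd_tbl,
        panels=list(series),
        distances=distances,
        comparisons=comparisons,
        embeddings=embeddings,
        correlation=correlation,
        version=__version__,
    )
    if config.outdir is not None:
        report.write(config.outdir)
    return report


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def render_figures(report: RunReport, outdir: str | Path, fmt: str = "svg") -> list:
    """Render the standard figure set; returns the written paths.

    One ranked-distance line chart per matrix comparison, a dual-series
    chart of mAFD and mutation rate over the locus ranking, and one MDS
    scatter per embedding.  Skips comparison charts when no comparison was
    computed.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    if not report.comparisons:
        logger.info("no matrix comparisons in report; skipping comparison figures")
    for label, cmp_ in report.comparisons.items():
        fig, ax = plt.subplots(figsize=(8, 4))
        x = np.arange(1, len(cmp_.pairs) + 1)
        ax.plot(x, cmp_.d_ref, label=cmp_.ref_name, lw=1)
        ax.plot(x, cmp_.d_alt, label=cmp_.alt_name, lw=1)
        ax.set_xlabel("population pair (ascending reference distance)")
        ax.set_ylabel("pairwise genetic distance")
        ax.legend()
        fig.tight_layout()
        path = out / f"ranked_distances_{label}.{fmt}"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)

    rows = report.mafd.rows
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(rows["locus"], rows["mafd"], marker="o", label="mAFD", color="tab:blue")
    ax.set_ylabel("mAFD")
    ax.set_xticks(range(len(rows)))
    ax.set_xticklabels(rows["locus"], rotation=90)
    if rows["mutation_rate"].notna().any():
        ax2 = ax.twinx()
        ax2.plot(
            rows["locus"], rows["mutation_rate"], marker="s",
            label="mutation rate", color="tab:orange",
        )
        ax2.set_ylabel("mutation rate / generation")
    fig.tight_layout()
    path = out / f"mafd_vs_mutation_rate.{fmt}"
    fig.savefig(path)
    plt.close(fig)
    written.append(path)

    for name, emb in report.embeddings.items():
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(emb.coords[:, 0], emb.coords[:, 1], s=12)
        for pop, (x, y) in zip(emb.populations, emb.coords):
            ax.annotate(str(pop), (x, y), fontsize=7, xytext=(2, 2),
                        textcoords="offset points")
        ax.set_xlabel("dimension 1")
        ax.set_ylabel("dimension 2")
        ax.set_title(f"{name} (stress-1 = {emb.stress:.3f}, {emb.method})")
        fig.tight_layout()
        path = out / f"mds_{name}.{fmt}"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
    return written
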