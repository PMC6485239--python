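"""End-to-end orchestration of the bioregionalization analysis.

Stages run in a fixed order — incidence validation, Jaccard distances,
percolation thresholding, simulated-annealing modularity with restart
consensus and a degree-preserving null test, locality roles and module
summaries, and (when species classes are available) between-group
correspondence analysis.  Every stochastic stage receives its own seed
derived deterministically from one master seed, so a rerun with identical
inputs and configuration reproduces every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import bgca as bgca_mod
from . import percolation as perc_mod
from .incidence import (
    IncidenceMatrix,
    SpeciesClassTable,
    read_incidence,
    read_species_classes,
    write_outputs,
)
from .modularity import (
    ModularityResult,
    Partition,
    SASchedule,
    WeightedGraph,
    best_partition,
    consensus,
    modularity_Q,
    null_distribution,
)
from .roles import (
    compute_roles,
    module_summaries,
    shared_species_ledger,
    species_module_map,
)
from .synth import MetacommunityConfig, generate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "run_pipeline_data",
           "run_synth", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from (master seed, name)."""
    digest = hashlib.blake2b(
        f"{master_seed}:{stage}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    incidence_path: str | None = None
    classes_path: str | None = None
    orientation: str = "species-rows"
    delimiter: str | None = None
    retention: str = "<"
    binary: bool = False
    n_restarts: int = 10
    n_rand: int = 1000
    l_cut: float = 1.0
    r_cut: float = 0.5
    seed: int = 0
    out_dir: str | None = None
    schedule: SASchedule = field(default_factory=SASchedule)
    null_schedule: SASchedule = field(default_factory=SASchedule.reduced)

    def __post_init__(self) -> None:
        if self.n_rand < 1:
            raise ValueError("n_rand must be >= 1")
        if self.n_restarts < 3:
            raise ValueError("n_restarts must be >= 3 (consensus needs 3)")


@dataclass
class RunReport:
    """Summary of one pipeline run; persisted as report.json."""

    config: dict
    threshold: float | None = None
    degenerate_threshold: bool = False
    n_links: int | None = None
    q: float | None = None
    restart_q_mean: float | None = None
    restart_q_sd: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    ci95: tuple | None = None
    p_value: float | None = None
    significant: bool | None = None
    n_modules: int | None = None
    module_summaries: list = field(default_factory=list)
    bgca_between_total_ratio: float | None = None
    bgca_pct_inertia: list = field(default_factory=list)
    stage_seeds: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    failed_stage: str | None = None
    error: str | None = None
    manifest: dict = field(default_factory=dict)


class _StageTimer:
    def __init__(self, report: RunReport, name: str):
        self.report, self.name = report, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        self.report.stage_seconds[self.name] = round(
            time.perf_counter() - self.t0, 3
        )
        if exc_type is not None:
            self.report.failed_stage = self.name
            self.report.error = f"{exc_type.__name__}: {exc}"
        return False


def run_pipeline_data(
    inc: IncidenceMatrix,
    classes: SpeciesClassTable | None,
    cfg: RunConfig,
) -> tuple[RunReport, dict]:
    """Run all stages on in-memory inputs; return (report, products).

    ``products`` maps artifact names to the in-memory objects (DataFrames,
    domain results); ``write_products`` / ``run_pipeline`` persist them.
    """
    report = RunReport(config=_config_dict(cfg))
    products: dict = {}

    with _StageTimer(report, "distances"):
        dm = perc_mod.jaccard_distances(inc)
        products["distances"] = pd.DataFrame(
            dm.d, index=dm.site_ids, columns=dm.site_ids
        ).reset_index(names="site")

    with _StageTimer(report, "percolation"):
        perc = perc_mod.percolation_threshold(dm, retention=cfg.retention)
        report.threshold = perc.threshold
        report.degenerate_threshold = perc.degenerate
        report.n_links = perc.n_links
        products["percolation_trace"] = pd.DataFrame(
            {
                "step": range(1, len(perc.trace) + 1),
                "removed_value": [s.removed_value for s in perc.trace],
                "n_components": [s.n_components for s in perc.trace],
                "largest": [s.largest for s in perc.trace],
                "avg_cluster_size": [s.avg_cluster_size for s in perc.trace],
            }
        )
        products["edges"] = pd.DataFrame(
            perc.retained_edges,
            columns=["source", "target", "distance", "similarity"],
        )
        products["_percolation"] = perc

    with _StageTimer(report, "modularity"):
        g = WeightedGraph.from_networkx(perc.graph(binary=cfg.binary))
        sa_seed = stage_seed(cfg.seed, "modularity")
        report.stage_seeds["modularity"] = sa_seed
        if g.m == 0:
            raise ValueError(
                "retained network has no links; cannot partition "
                "(degenerate percolation threshold)"
            )
        _, best_q, parts, qs = best_partition(
            g, n_restarts=cfg.n_restarts, schedule=cfg.schedule, seed=sa_seed
        )
        cons, freq = consensus(parts)
        q_cons = modularity_Q(g, cons)
        # the consensus is reported unless a restart strictly beats it
        if best_q > q_cons + 1e-9:
            ibest = max(range(len(qs)), key=lambda i: qs[i])
            part, q = parts[ibest], qs[ibest]
        else:
            part, q = cons, q_cons
        qs_series = pd.Series(qs)
        report.q = q
        report.restart_q_mean = float(qs_series.mean())
        report.restart_q_sd = float(qs_series.std(ddof=1))
        report.n_modules = part.n_modules
        products["modules"] = pd.DataFrame(
            {
                "site": list(inc.site_ids),
                "module": [part[s] for s in inc.site_ids],
                "affiliation_freq": [freq[s] for s in inc.site_ids],
            }
        )
        products["_graph"], products["_partition"] = g, part

    with _StageTimer(report, "null_model"):
        null_seed = stage_seed(cfg.seed, "null_model")
        report.stage_seeds["null_model"] = null_seed
        null = null_distribution(
            g, q, n_rand=cfg.n_rand, seed=null_seed, schedule=cfg.null_schedule
        )
        report.null_mean = null["null_mean"]
        report.null_sd = null["null_sd"]
        report.ci95 = null["ci95"]
        report.p_value = null["p_value"]
        report.significant = bool(q > null["ci95"][1])
        products["null_Q"] = pd.DataFrame({"null_q": null["null_q"]})
        products["modularity"] = {
            "q": q,
            "restart_q_mean": report.restart_q_mean,
            "restart_q_sd": report.restart_q_sd,
            "n_modules": report.n_modules,
            **{k: null[k] for k in ("null_mean", "null_sd", "ci95",
                                    "p_value", "n_rand")},
            "seeds": report.stage_seeds,
        }
        products["_modularity_result"] = ModularityResult(
            partition=part, q=q, restart_qs=qs, affiliation_freq=freq,
            null_q=null["null_q"], null_mean=null["null_mean"],
            null_sd=null["null_sd"], ci95=null["ci95"],
            p_value=null["p_value"],
        )

    with _StageTimer(report, "roles"):
        smm = species_module_map(inc, part)
        products["roles"] = compute_roles(
            inc, part, smm, cuts=(cfg.l_cut, cfg.r_cut)
        )
        summaries = module_summaries(inc, part, smm, classes)
        products["module_summary"] = summaries
        products["shared_species"] = shared_species_ledger(smm)
        report.module_summaries = summaries.to_dict(orient="records")

    if classes is not None:
        with _StageTimer(report, "bgca"):
            counts = bgca_mod.class_counts(inc, classes)
            res = bgca_mod.between_group_ca(counts, part)
            report.bgca_between_total_ratio = res.between_total_ratio
            report.bgca_pct_inertia = [float(x) for x in res.pct_inertia]
            products["class_counts"] = counts.reset_index(names="site")
            products["bgca_eigen"] = pd.DataFrame(
                {
                    "axis": [f"CA{i+1}" for i in range(len(res.eigenvalues))],
                    "eigenvalue": res.eigenvalues,
                    "pct_inertia": res.pct_inertia,
                }
            )
            products["bgca_sites"] = res.site_scores.reset_index(names="site")
            classes_df = res.class_scores.add_prefix("score_").join(
                res.class_contrib.add_prefix("contrib_")
            )
            products["bgca_classes"] = classes_df.reset_index(names="class")
            products["bgca"] = {
                "between_inertia": res.between_inertia,
                "total_inertia": res.total_inertia,
                "between_total_ratio": res.between_total_ratio,
                "eigenvalues": list(res.eigenvalues),
                "pct_inertia": [float(x) for x in res.pct_inertia],
            }
            products["_bgca_result"] = res

    return report, products


def write_products(
    report: RunReport, products: dict, out_dir: str | Path
) -> dict[str, int]:
    """Persist public products (non-underscore keys) plus the run report."""
    out_dir = Path(out_dir)
    public = {k: v for k, v in products.items() if not k.startswith("_")}
    manifest = write_outputs(public, out_dir)
    perc = products.get("_percolation")
    if perc is not None:
        nx.write_graphml(perc.graph(), out_dir / "network.graphml")
        manifest["network.graphml"] = perc.n_links
    report.manifest = manifest
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(report), fh, indent=2, default=str)
    return manifest


def run_pipeline(cfg: RunConfig) -> RunReport:
    """File-to-file pipeline run: read inputs, run stages, write artifacts."""
    if cfg.incidence_path is None:
        raise ValueError("incidence_path is required")
    inc = read_incidence(
        cfg.incidence_path, orientation=cfg.orientation, delimiter=cfg.delimiter
    )
    classes = None
    if cfg.classes_path is not None:
        classes = read_species_classes(cfg.classes_path, delimiter=cfg.delimiter)
    report, products = run_pipeline_data(inc, classes, cfg)
    if cfg.out_dir is not None:
        write_products(report, products, cfg.out_dir)
    return report


def run_synth(config: MetacommunityConfig, out_dir: str | Path) -> dict[str, int]:
    """Generate a synthetic metacommunity and write it in pipeline formats."""
    inc, truth, classes = generate(config)
    out_dir = Path(out_dir)
    manifest = write_outputs(
        {"incidence": inc, "species_classes": classes}, out_dir
    )
    truth_doc = {"true_partition": truth, "config": asdict(config)}
    with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_doc, fh, indent=2)
    manifest["truth.json"] = len(truth)
    return manifest


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d
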