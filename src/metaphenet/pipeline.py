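"""End-to-end orchestration: simulate -> differential -> integrate -> network -> centrality.

The pipeline is a pure function of its configuration: every stage draws
only on the run config and the previous stages' outputs, and all writers
are deterministic, so re-running with the same config reproduces
byte-identical outputs (the manifest's stage timings excepted).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from . import centrality as centrality_mod
from . import clr as clr_mod
from . import io as io_mod
from .config import ClrConfig, ConfigurationError, DiffExprConfig, SyntheticConfig
from .diffexpr import call_overexpressed, differential_expression
from .integration import (
    build_terminals,
    condition_gene_sets,
    minimal_subnetwork,
    unique_genes,
)
from .network import MetabolicNetwork
from .synthetic import (
    PlantedTruth,
    detections_from_frame,
    detections_to_frame,
    generate_expression,
    generate_master_network,
    generate_metabolite_detections,
    sample_conditions,
    sample_sites,
)

log = logging.getLogger(__name__)

EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.\d+$")


@dataclass
class RunConfig:
    """Everything a run needs: inputs (real paths or a synthetic block),
    stage configurations, output directory and seed."""

    outdir: Path
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    expression_path: Path | None = None
    metabolites_path: Path | None = None
    network_path: Path | None = None
    control: str = "control"
    diffexpr: DiffExprConfig = field(default_factory=DiffExprConfig)
    clr: ClrConfig = field(default_factory=ClrConfig)
    neighborhood_condition: str | None = None
    make_plots: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        real = all(
            p is not None
            for p in (self.expression_path, self.metabolites_path, self.network_path)
        )
        if self.synthetic is None and not real:
            raise ConfigurationError(
                "either a synthetic block or all three input paths "
                "(expression, metabolites, network) must be provided"
            )
        if self.synthetic is not None and self.synthetic.seed != self.seed:
            # one seed governs the whole run
            self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)
        if self.synthetic is not None:
            self.control = self.synthetic.control

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "synthetic" in raw:
            kwargs["synthetic"] = SyntheticConfig(**raw.pop("synthetic"))
        if "diffexpr" in raw:
            kwargs["diffexpr"] = DiffExprConfig(**raw.pop("diffexpr"))
        if "clr" in raw:
            clr_raw = dict(raw.pop("clr"))
            kwargs["clr"] = ClrConfig(**clr_raw)
        for key in ("expression_path", "metabolites_path", "network_path"):
            if key in raw:
                kwargs[key] = Path(raw.pop(key))
        kwargs.update(raw)
        if "outdir" not in kwargs:
            raise ConfigurationError("config must set outdir")
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return {
        f.name: convert(getattr(config, f.name)) for f in dataclasses.fields(config)
    }


def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Schema and cross-reference checks on an expression/metabolites/network trio.

    Returns a machine-readable issue list; an empty list means all checks
    passed. Levels are ``error`` (the pipeline would misbehave) and
    ``warning`` (ids that will be dropped with a report).
    """
    issues: list[dict] = []

    def issue(level: str, message: str, location: str) -> None:
        issues.append({"level": level, "message": message, "location": location})

    resolved: dict[str, Path] = {}
    for key in ("expression", "metabolites", "network"):
        if key not in paths:
            issue("error", f"missing input path for {key}", key)
            continue
        p = Path(paths[key])
        if not p.is_file():
            issue("error", f"unreadable file: {p}", key)
        else:
            resolved[key] = p
    if set(resolved) != {"expression", "metabolites", "network"}:
        return issues

    network = None
    try:
        network = MetabolicNetwork.from_tsv(resolved["network"])
    except Exception as exc:  # noqa: BLE001 - report, don't crash validation
        issue("error", f"network parse failure: {exc}", "network")

    try:
        expr = pd.read_csv(resolved["expression"], sep="\t", index_col=0)
        dupes = expr.index[expr.index.duplicated()]
        for gene in dupes:
            row = int(list(expr.index).index(gene)) + 2
            issue("error", f"duplicated gene row {gene!r} (line {row})", "expression")
        for gene in expr.index:
            if not EC_PATTERN.match(str(gene)):
                issue("warning", f"gene id {gene!r} is not EC-style", "expression")
        try:
            sample_conditions(expr.columns)
        except ValueError as exc:
            issue("error", str(exc), "expression")
    except Exception as exc:  # noqa: BLE001
        issue("error", f"expression parse failure: {exc}", "expression")

    try:
        mets = pd.read_csv(resolved["metabolites"], sep="\t")
        if not {"condition", "metabolite_id"}.issubset(mets.columns):
            issue(
                "error",
                "metabolite table needs columns condition, metabolite_id",
                "metabolites",
            )
        elif network is not None:
            known = network.metabolites
            for met in sorted(set(mets["metabolite_id"].astype(str)) - known):
                issue("warning", f"metabolite {met!r} absent from network", "metabolites")
    except Exception as exc:  # noqa: BLE001
        issue("error", f"metabolite parse failure: {exc}", "metabolites")

    return issues


def _load_inputs(config: RunConfig, outdir: Path):
    """Simulate or read the input trio; returns (expr, detections, network, truth)."""
    if config.synthetic is not None:
        syn = config.synthetic
        network = generate_master_network(syn)
        expr, truth = generate_expression(syn, network)
        detections = generate_metabolite_detections(network, truth, syn)
        network.to_tsv(outdir / "reactions.tsv")
        io_mod.write_expression(expr, outdir / "expression.tsv")
        detections_to_frame(detections).to_csv(
            outdir / "metabolites.tsv", sep="\t", index=False
        )
        truth.to_json(outdir / "truth.json")
        return expr, detections, network, truth
    issues = validate_inputs(
        {
            "expression": config.expression_path,
            "metabolites": config.metabolites_path,
            "network": config.network_path,
        }
    )
    errors = [i for i in issues if i["level"] == "error"]
    if errors:
        raise ConfigurationError(f"input validation failed: {errors}")
    expr = io_mod.read_expression(config.expression_path)
    detections = detections_from_frame(
        pd.read_csv(config.metabolites_path, sep="\t", dtype=str)
    )
    network = MetabolicNetwork.from_tsv(config.network_path)
    return expr, detections, network, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_echo(config),
        "version": __version__,
        "stages": [],
        "warnings": [],
        "status": "running",
    }

    def finish_stage(name: str, started: float, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "name": name,
                "seconds": round(time.perf_counter() - started, 3),
                "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
            }
        )

    try:
        t0 = time.perf_counter()
        expr, detections, network, truth = _load_inputs(config, outdir)
        stage_outputs = [
            p
            for p in (
                outdir / "reactions.tsv",
                outdir / "expression.tsv",
                outdir / "metabolites.tsv",
                outdir / "truth.json",
            )
            if p.exists()
        ]
        finish_stage("inputs", t0, stage_outputs)

        conds = sample_conditions(expr.columns)
        sites = sample_sites(expr.columns)
        conditions = sorted(set(conds))
        if config.control not in conditions:
            raise ConfigurationError(
                f"control condition {config.control!r} absent from samples"
            )
        perturbations = [c for c in conditions if c != config.control]
        site_names = sorted(set(sites))

        # differential expression per perturbation x site
        t0 = time.perf_counter()
        overexpressed: dict[tuple[str, str], set[str]] = {}
        de_outputs: list[Path] = []
        for cond in perturbations:
            for site in site_names:
                cols = [
                    c
                    for c in expr.columns
                    if (conds[c] == cond or conds[c] == config.control)
                    and sites[c] == site
                ]
                sub = expr[cols]
                if not any(conds[c] == cond for c in cols):
                    continue
                result = differential_expression(
                    sub, cond, config.control, config.diffexpr
                )
                path = outdir / f"differential_{cond}_{site}.tsv"
                result.to_csv(path, sep="\t", index_label="gene")
                de_outputs.append(path)
                overexpressed[(cond, site)] = call_overexpressed(
                    result, config.diffexpr
                )
        finish_stage("differential", t0, de_outputs)

        # metabolic integration per condition x site (control: metabolites only)
        t0 = time.perf_counter()
        int_outputs: list[Path] = []
        results = []
        for cond in conditions:
            for site in site_names:
                over = overexpressed.get((cond, site), set())
                terminals = build_terminals(
                    network, detections.get(cond, []), over
                )
                res = minimal_subnetwork(network, terminals, condition=cond, site=site)
                manifest["warnings"].extend(
                    f"{cond}/{site}: {w}" for w in res.warnings
                )
                path = outdir / f"subnetwork_{cond}_{site}.sif"
                io_mod.write_sif(res.edges, path, interaction="mr")
                int_outputs.append(path)
                results.append(res)
        table = condition_gene_sets(results)
        uniques = unique_genes(table)
        genes_path = outdir / "condition_genes.tsv"
        table.to_frame().to_csv(genes_path, sep="\t", index=False)
        int_outputs.append(genes_path)
        finish_stage("integration", t0, int_outputs)

        # CLR co-expression network over all conditions
        t0 = time.perf_counter()
        scores = clr_mod.compute_scores(expr, config.clr)
        if config.clr.target_edges is not None:
            net = clr_mod.top_k_network(scores, config.clr.target_edges)
        else:
            net = clr_mod.threshold_network(scores, config.clr.z_threshold)
        component = clr_mod.largest_component(net)
        summary = {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "component_nodes": component.number_of_nodes(),
            "component_edges": component.number_of_edges(),
            "component_sizes": sorted(
                (len(c) for c in nx.connected_components(net)), reverse=True
            ),
            "excluded_genes": scores.excluded,
            "provenance": net.graph.get("provenance", ""),
        }
        try:
            exponent, r2 = clr_mod.powerlaw_fit(component)
            summary["powerlaw_exponent"] = round(exponent, 6)
            summary["powerlaw_r2"] = round(r2, 6)
        except ValueError as exc:
            summary["powerlaw_error"] = str(exc)
        io_mod.write_sif(net.edges, outdir / "network.sif")
        io_mod.write_edge_tsv(net.edges, outdir / "network_edges.tsv")
        io_mod.write_graphml(net, outdir / "network.graphml")
        io_mod.write_json(summary, outdir / "network_summary.json")
        finish_stage(
            "network",
            t0,
            [
                outdir / "network.sif",
                outdir / "network_edges.tsv",
                outdir / "network.graphml",
                outdir / "network_summary.json",
            ],
        )

        # centrality analysis on the main component
        t0 = time.perf_counter()
        cen_outputs: list[Path] = []
        ctable = centrality_mod.compute_centralities(component)
        ctable_path = outdir / "centrality.tsv"
        ctable.to_csv(ctable_path, sep="\t")
        cen_outputs.append(ctable_path)
        labels = {c: set(uniques.get(c, frozenset())) for c in perturbations}
        gsummary = centrality_mod.group_summary(ctable, labels)
        gpath = outdir / "group_summary.tsv"
        gsummary.to_csv(gpath, sep="\t")
        cen_outputs.append(gpath)
        ratios = centrality_mod.ratio_to_median(ctable)
        rpath = outdir / "centrality_ratios.tsv"
        ratios.to_csv(rpath, sep="\t")
        cen_outputs.append(rpath)
        seed_cond = config.neighborhood_condition or (
            perturbations[0] if perturbations else None
        )
        if seed_cond is not None:
            hood = centrality_mod.neighborhood_subnetwork(
                component, labels.get(seed_cond, set()), drop_isolated_seeds=True
            )
            hpath = outdir / f"neighborhood_{seed_cond}.sif"
            io_mod.write_sif(hood.edges, hpath)
            cen_outputs.append(hpath)
        if config.make_plots:
            plot_path = outdir / "centrality_ratios.svg"
            _plot_ratios(ratios, labels, plot_path)
            cen_outputs.append(plot_path)
        finish_stage("centrality", t0, cen_outputs)

        manifest["status"] = "completed"
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        io_mod.write_json(manifest, outdir / "manifest.json")
        raise
    io_mod.write_json(manifest, outdir / "manifest.json")
    return manifest


def _plot_ratios(ratios: pd.DataFrame, labels: dict[str, set[str]], path: Path) -> None:
    """Degree-ratio vs log2 betweenness-ratio scatter with condition overlays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "metaphenet"
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(
        ratios["degree_ratio"], ratios["log2_betweenness_ratio"],
        s=8, c="0.7", label="all genes",
    )
    palette = ["tab:red", "tab:blue", "tab:orange", "tab:green", "tab:purple"]
    for color, cond in zip(palette, sorted(labels)):
        genes = [g for g in sorted(labels[cond]) if g in ratios.index]
        if genes:
            ax.scatter(
                ratios.loc[genes, "degree_ratio"],
                ratios.loc[genes, "log2_betweenness_ratio"],
                s=24, c=color, label=cond,
            )
    ax.set_xlabel("degree / median degree")
    ax.set_ylabel("log2(betweenness / median betweenness)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
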