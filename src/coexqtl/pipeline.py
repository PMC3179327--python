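"""End-to-end orchestration: configuration, validation, stage running.

``run_pipeline`` chains simulate (optional) → filter → network → trait
relation → genome scan → hotspot detection, writing every stage's output as
plain text plus a JSON run report.  Each output file carries a header comment
with the tool version, seed and a hash of the configuration, so re-running
with the same configuration reproduces content byte for byte (timestamps
live only in the report).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    ValidationError,
    read_expression, read_genotypes, read_traits,
    write_expression, write_genotypes, write_traits,
)
from .preprocess import detection_filter, variance_filter
from .network import (
    correlation_matrix, export_edges, hub_genes, pick_soft_power,
    soft_adjacency, topological_overlap, cluster_genes, dynamic_tree_cut,
    connectivities, ModuleAssignment, UNASSIGNED,
)
from .traits import module_trait_table, module_eigengene, trait_trait_correlation
from .qtl import genome_scan, merge_crosses
from .hotspots import hotspot_table, call_hotspots
from .simulate import SimConfig, simulate_panel, split_by_cross

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run; serializable to/from YAML."""

    # filtering
    alpha_detect: float = 0.01
    min_detect_fraction: float = 0.5
    top_k: int = 3600
    # network
    beta: float | str = 6.0  # numeric, or "auto" for the scale-free criterion
    fit_threshold: float = 0.8
    min_module_size: int = 30
    cut_height_quantile: float = 0.99
    # eQTL / hotspots
    lrs_cutoff: float = 13.8
    n_perm_scan: int = 1000
    n_perm_hotspot: int = 10000
    alpha_hotspot: float = 0.05
    # randomness
    seed: int = 0
    # inputs (ignored when simulate=True)
    simulate: bool = True
    expression_path: str | None = None
    detection_path: str | None = None
    genotype_paths: tuple[str, ...] = ()
    trait_path: str | None = None
    strict_genotype: bool = False
    # simulator settings used when simulate=True
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # YAML has no tuples; normalize sequence-valued simulator settings so
        # load(save(config)) == config
        def norm(v):
            if isinstance(v, (list, tuple)):
                return tuple(norm(x) for x in v)
            return v

        self.sim = {k: norm(v) for k, v in self.sim.items()}

    def validate(self) -> None:
        if not 0 < self.alpha_detect < 1:
            raise ValidationError("alpha_detect must lie in (0, 1)")
        if not 0 < self.min_detect_fraction <= 1:
            raise ValidationError("min_detect_fraction must lie in (0, 1]")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.beta != "auto" and float(self.beta) <= 0:
            raise ValidationError("beta must be positive or 'auto'")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")
        if not 0 < self.cut_height_quantile <= 1:
            raise ValidationError("cut_height_quantile must lie in (0, 1]")
        if self.lrs_cutoff <= 0:
            raise ValidationError("lrs_cutoff must be positive")
        if not 0 < self.alpha_hotspot < 1:
            raise ValidationError("alpha_hotspot must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["genotype_paths"] = list(self.genotype_paths)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "genotype_paths" in payload:
            payload["genotype_paths"] = tuple(payload["genotype_paths"])
        return cls(**payload)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["genotype_paths"] = list(self.genotype_paths)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_inputs(
    expression_path=None, detection_path=None, genotype_paths=(),
    trait_path=None, strict_genotype: bool = False,
) -> list[dict]:
    """Structural validation of the pipeline's input files.

    Returns a machine-readable issue list; entries carry ``level`` ("error"
    or "warning") and a message.  Checks: files parse, expression/detection
    shapes agree, strain ids overlap across tables, allele codes are legal,
    cM positions are monotone within chromosome.
    """
    issues: list[dict] = []

    def err(msg, **kw):
        issues.append({"level": "error", "message": msg, **kw})

    def warn(msg, **kw):
        issues.append({"level": "warning", "message": msg, **kw})

    expr = genos = traits = None
    if expression_path:
        try:
            expr = read_expression(expression_path, detection_path)
        except Exception as e:  # noqa: BLE001 - reported, not raised
            err(f"expression unreadable: {e}", file=str(expression_path))
    genos = []
    for gp in genotype_paths:
        try:
            genos.append(read_genotypes(gp, strict=strict_genotype))
        except Exception as e:  # noqa: BLE001
            err(f"genotype unreadable: {e}", file=str(gp))
    if trait_path:
        try:
            traits = read_traits(trait_path)
        except Exception as e:  # noqa: BLE001
            err(f"traits unreadable: {e}", file=str(trait_path))

    if expr is not None and traits is not None:
        missing = set(traits.strain_ids) - set(expr.strain_ids)
        for s in sorted(missing):
            warn(f"strain {s} present in traits but not expression", strain=s)
        if not set(traits.strain_ids) & set(expr.strain_ids):
            err("no strain overlap between traits and expression")
    if expr is not None and genos:
        geno_strains = {s for g in genos for s in g.strain_ids}
        if not geno_strains & set(expr.strain_ids):
            err("no strain overlap between genotypes and expression")
    return issues


def _write_df(df: pd.DataFrame, path: Path, header: str, index_label: str,
              sep: str = "\t", float_format: str | None = "%.6g") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep=sep, index_label=index_label, na_rep=".",
                  float_format=float_format)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and return the run report (also written to
    ``report.json`` in ``outdir``).

    On stage failure a :class:`StageError` names the failed stage; outputs of
    completed stages are retained and ``MANIFEST.json`` records completion
    state.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"coexqtl {__version__} | seed={config.seed} | config={config.config_hash()}"
    manifest: dict[str, str] = {}
    report: dict = {"version": __version__, "seed": config.seed,
                    "config_hash": config.config_hash(),
                    "parameters": {k: v for k, v in asdict(config).items() if k != "sim"}}
    t0 = time.perf_counter()

    def finish_stage(name: str) -> None:
        manifest[name] = "complete"
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))

    def fail(name: str, exc: Exception):
        manifest[name] = f"failed: {exc}"
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
        raise StageError(name, exc) from exc

    # ---- inputs ----------------------------------------------------------
    try:
        if config.simulate:
            sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
            geno_all, expr, traits, truth = simulate_panel(sim_cfg)
            geno_tables = list(split_by_cross(geno_all).values())
            write_expression(expr, outdir / "expression.tsv",
                             outdir / "detection.tsv", header)
            for gt in geno_tables:
                label = gt.cross.iloc[0] if gt.cross is not None else "ALL"
                write_genotypes(gt, outdir / f"genotypes_{label}.tsv", header)
            write_traits(traits, outdir / "traits.csv", header)
            truth.to_json(outdir / "truth.json")
            report["simulation"] = {"hotspot_marker": truth.hotspot_marker_id,
                                    "trait_module": truth.trait_module_id}
        else:
            if not (config.expression_path and config.genotype_paths):
                raise ValidationError("expression and genotype paths required")
            issues = validate_inputs(
                config.expression_path, config.detection_path,
                config.genotype_paths, config.trait_path,
                config.strict_genotype,
            )
            if any(i["level"] == "error" for i in issues):
                raise ValidationError(f"input validation failed: {issues}")
            expr = read_expression(config.expression_path, config.detection_path)
            geno_tables = [read_genotypes(p, strict=config.strict_genotype)
                           for p in config.genotype_paths]
            traits = read_traits(config.trait_path) if config.trait_path else None
            truth = None
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        fail("inputs", e)
    finish_stage("inputs")

    # ---- filter ----------------------------------------------------------
    try:
        n_input = expr.n_genes
        if expr.detection_p is not None:
            expr = detection_filter(expr, config.alpha_detect, config.min_detect_fraction)
        n_detected = expr.n_genes
        expr = variance_filter(expr, config.top_k)
        report["filter"] = {"n_input": n_input, "n_detected": n_detected,
                            "n_selected": expr.n_genes}
        write_expression(expr, outdir / "filtered_expression.tsv", None, header)
    except Exception as e:  # noqa: BLE001
        fail("filter", e)
    finish_stage("filter")

    # ---- network ---------------------------------------------------------
    try:
        cor = correlation_matrix(expr)
        if config.beta == "auto":
            beta, fit = pick_soft_power(cor, fit_threshold=config.fit_threshold)
            _write_df(fit, outdir / "soft_power_fit.csv", header, "row", sep=",")
        else:
            beta = float(config.beta)
        adj = soft_adjacency(cor, beta)
        tom = topological_overlap(adj)
        dendro = cluster_genes(tom)
        labels = dynamic_tree_cut(dendro, config.min_module_size,
                                  config.cut_height_quantile)
        k = connectivities(adj, labels)
        assignment = ModuleAssignment(pd.concat([labels, k], axis=1))
        sizes = assignment.module_sizes()
        report["network"] = {
            "beta": beta,
            "n_modules": int(sum(1 for m in sizes.index if m != UNASSIGNED)),
            "module_sizes": {m: int(s) for m, s in sizes.items()},
        }
        _write_df(assignment.table, outdir / "modules.tsv", header, "gene_id")
        (outdir / "dendrogram.newick").write_text(dendro.to_newick() + "\n")
        _write_df(hub_genes(assignment), outdir / "hub_genes.tsv", header, "row")
    except Exception as e:  # noqa: BLE001
        fail("network", e)
    finish_stage("network")

    # ---- trait relation --------------------------------------------------
    focus_module = None
    if traits is not None:
        try:
            mt = module_trait_table(expr, assignment, traits)
            _write_df(mt, outdir / "module_trait.csv", header, "row", sep=",",
                      float_format=None)
            tc = trait_trait_correlation(traits)
            _write_df(tc, outdir / "trait_correlations.csv", header, "row",
                      sep=",", float_format=None)
            eig_rows = {}
            for module in assignment.module_names:
                eig, ve = module_eigengene(expr, assignment.members(module))
                eig_rows[module] = pd.concat(
                    [eig, pd.Series({"variance_explained": ve})]
                )
            _write_df(pd.DataFrame(eig_rows).T, outdir / "eigengenes.csv",
                      header, "module", sep=",")
            if len(mt):
                ranking = mt.groupby("module")["MS"].mean().sort_values(ascending=False)
                focus_module = str(ranking.index[0])
                edges = export_edges(cor, assignment.members(focus_module))
                _write_df(edges, outdir / "edges.tsv", header, "row")
            report["module_trait"] = {
                "focus_module": focus_module,
                "table": mt.to_dict(orient="records"),
            }
        except Exception as e:  # noqa: BLE001
            fail("traits", e)
        finish_stage("traits")

    # ---- genome scan -----------------------------------------------------
    try:
        geno = merge_crosses(geno_tables)
        scan = genome_scan(expr, geno, n_perm=config.n_perm_scan,
                           seed=config.seed)
        _write_df(scan.lrs, outdir / "lrs_matrix.tsv", header, "gene_id")
        trip = scan.lrs.stack().rename("lrs").reset_index()
        trip.columns = ["gene_id", "marker", "lrs"]
        trip = trip[trip["lrs"] > config.lrs_cutoff].copy()
        trip["lod"] = trip["lrs"] / 4.6
        _write_df(trip, outdir / "lrs_triplets.tsv", header, "row")
        if scan.thresholds is not None:
            _write_df(scan.thresholds, outdir / "scan_thresholds.csv", header,
                      "gene_id", sep=",", float_format=None)
        report["scan"] = {
            "n_markers": int(scan.lrs.shape[1]),
            "n_cells_above_cutoff": int(len(trip)),
        }
    except Exception as e:  # noqa: BLE001
        fail("scan", e)
    finish_stage("scan")

    # ---- hotspots --------------------------------------------------------
    try:
        if focus_module is None and assignment.module_names:
            focus_module = assignment.module_names[0]
        if focus_module is not None:
            hs = hotspot_table(
                scan, assignment.members(focus_module), module=focus_module,
                cutoff=config.lrs_cutoff, n_perm=config.n_perm_hotspot,
                seed=config.seed,
            )
            flagged = call_hotspots(hs, config.alpha_hotspot)
            out = hs.table.copy()
            out["flagged"] = out.index.isin(flagged.index)
            _write_df(out, outdir / "hotspots.csv", header, "marker", sep=",",
                      float_format=None)
            (outdir / "hotspot_metadata.json").write_text(
                json.dumps(hs.metadata(), indent=1)
            )
            report["hotspots"] = {
                "module": focus_module,
                "flagged_markers": list(flagged.index),
            }
    except Exception as e:  # noqa: BLE001
        fail("hotspots", e)
    finish_stage("hotspots")

    report["wall_time_s"] = round(time.perf_counter() - t0, 3)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
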