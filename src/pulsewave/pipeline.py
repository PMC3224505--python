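"""End-to-end orchestration: simulate/load -> correlate -> diffexpr ->
cluster -> NP network -> enrichment -> report.

A single :class:`RunConfig` (YAML-serializable) drives every stage.  One
global seed fans out to per-stage sub-seeds by stable hashing, so any stage
can be re-run in isolation and two runs with the same config produce
byte-identical reports.  Every intermediate artifact is written to the
output directory and hashed into a MANIFEST.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .clustering import hier_cluster, som_cluster
from .enrichment import dp_enrich, hypergeom_enrich
from .npnet import classify_hubs, find_modules, inter_module_summary, interface_core, reduce_network
from .synthetic import (
    ArchetypeSpec,
    ModuleSpec,
    PlantedDesign,
    default_design,
    default_time_grid,
    simulate_annotations,
    simulate_expression,
    simulate_network,
)

__all__ = ["RunConfig", "StageError", "run_pipeline", "stage_seed"]

REPORT_SCHEMA_VERSION = 1

STAGES = ("data", "correlate", "diffexpr", "cluster", "npnet", "enrich")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML.

    Either ``inputs`` names the three input files (expression, network,
    annotations) or ``simulate`` describes a planted design (``null`` uses
    the package default).  Stage parameter dictionaries carry only the keys
    the user overrides; defaults are filled at run time and echoed in the
    report.
    """

    outdir: str = "pulsewave_run"
    seed: int = 0
    inputs: dict | None = None
    simulate: dict | None = field(default_factory=dict)
    diffexpr: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    npnet: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)
    skip: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.inputs is None and self.simulate is None:
            raise ValueError("config needs either 'inputs' or a 'simulate' block")
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) in skip: {sorted(unknown)}")
        for name in ("diffexpr", "cluster", "npnet", "enrich"):
            block = getattr(self, name)
            bad = set(block) - set(_DEFAULTS[name])
            if bad:
                raise ValueError(f"unknown {name} parameter(s): {sorted(bad)}")

    def resolved(self, stage: str) -> dict:
        params = dict(_DEFAULTS[stage])
        params.update(getattr(self, stage))
        return params

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")


_DEFAULTS = {
    "diffexpr": {"df_spline": 4, "n_perm": 2000, "alpha": 1e-3, "correction": "bonferroni"},
    "cluster": {
        "som_rows": 2,
        "som_cols": 4,
        "n_iter": 500,
        "ci_level": 0.95,
        "max_outside_frac": 0.2,
        "hier_similarity": 0.5,
    },
    "npnet": {"pcc_threshold": 0.7, "max_anti_frac": 0.01, "min_hub_degree": 5},
    "enrich": {"alpha": 1e-3, "dp_formula": "n2_over_t"},
}

_SIM_DEFAULTS = {"p_intra": 0.3, "p_inter": 0.02, "n_tf": 20, "frac_in": 0.8, "frac_bg": 0.05}


def _design_from_config(block: dict, seed: int) -> PlantedDesign:
    if not block or "modules" not in block:
        base = default_design(seed)
        return PlantedDesign(
            modules=base.modules,
            noise_sd=block.get("noise_sd", base.noise_sd),
            seed=seed,
            n_background_flat=block.get("n_background_flat", base.n_background_flat),
        )
    modules = tuple(
        ModuleSpec(
            size=m["size"],
            archetype=ArchetypeSpec(**m["archetype"]),
            signs=m.get("signs", 1),
        )
        for m in block["modules"]
    )
    return PlantedDesign(
        modules=modules,
        noise_sd=block.get("noise_sd", 0.1),
        seed=seed,
        n_background_flat=block.get("n_background_flat", 0),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(obj):
    """Coerce numpy scalars so report artifacts serialize cleanly."""
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the JSON report.

    Artifacts and ``report.json`` land in ``config.outdir``; a MANIFEST
    records completed stages and the SHA-256 of every artifact.  Any stage
    failure raises :class:`StageError` after the MANIFEST of completed
    stages has been written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    artifacts: dict[str, str] = {}
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "skipped_stages": sorted(config.skip),
    }

    def finish_stage(stage: str, files: list[Path]) -> None:
        for f in files:
            artifacts[f.name] = _sha256(f)
        completed.append(stage)

    def write_manifest() -> None:
        manifest = {"completed_stages": completed, "artifacts": artifacts}
        (outdir / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n", encoding="utf-8"
        )

    def guard(stage: str, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:
            write_manifest()
            raise StageError(stage, str(exc)) from exc

    # ---- data -------------------------------------------------------------
    def _data():
        files = []
        if config.inputs is not None:
            expr = pio.read_expression(config.inputs["expression"])
            network = pio.read_network(config.inputs["network"])
            annotations = pio.read_annotations(config.inputs["annotations"])
            truth = None
        else:
            sim = dict(_SIM_DEFAULTS)
            sim.update({k: v for k, v in (config.simulate or {}).items()
                        if k in _SIM_DEFAULTS})
            design = _design_from_config(config.simulate or {}, stage_seed(config.seed, "design"))
            grid = default_time_grid()
            expr, truth = simulate_expression(design, grid)
            network = simulate_network(
                truth, sim["p_intra"], sim["p_inter"], sim["n_tf"],
                seed=stage_seed(config.seed, "network"),
            )
            annotations = simulate_annotations(
                truth, frac_in=sim["frac_in"], frac_bg=sim["frac_bg"],
                seed=stage_seed(config.seed, "annotations"),
            )
            pio.write_expression(expr, outdir / "expression.tsv")
            pio.write_network(network, outdir / "network.tsv")
            pio.write_annotations(annotations, outdir / "annotations.tsv")
            _write_tsv(truth, outdir / "truth.tsv")
            files = [outdir / n for n in
                     ("expression.tsv", "network.tsv", "annotations.tsv", "truth.tsv")]
        report["data"] = {
            "n_genes": expr.n_genes,
            "n_samples": len(expr.grid),
            "n_network_nodes": len(network.nodes),
            "n_network_edges": network.n_edges,
            "n_annotation_pairs": len(annotations),
            "simulated": config.inputs is None,
        }
        finish_stage("data", files)
        return expr, network, annotations, truth

    expr, network, annotations, truth = guard("data", _data)

    # ---- correlate --------------------------------------------------------
    profile = None
    if "correlate" not in config.skip:
        def _correlate():
            from .timecourse import correlation_profile

            prof = correlation_profile(expr)
            _write_tsv(prof, outdir / "correlation_profile.tsv")
            report["correlation_profile"] = {
                "labels": prof["label"].tolist(),
                "pcc": [round(float(x), 10) for x in prof["pcc"]],
            }
            finish_stage("correlate", [outdir / "correlation_profile.tsv"])
            return prof

        profile = guard("correlate", _correlate)

    # ---- diffexpr ---------------------------------------------------------
    sig_genes: list[str] = []
    if "diffexpr" not in config.skip:
        def _diffexpr():
            from .timecourse import within_class_test

            params = config.resolved("diffexpr")
            table = within_class_test(
                expr,
                df_spline=params["df_spline"],
                n_perm=params["n_perm"],
                seed=stage_seed(config.seed, "diffexpr"),
                alpha=params["alpha"],
                correction=params["correction"],
            )
            _write_tsv(table, outdir / "significance.tsv")
            sig = table.loc[table["significant"], "gene_id"].tolist()
            report["significance"] = {
                "params": params,
                "n_genes_tested": int(len(table)),
                "n_significant": len(sig),
            }
            finish_stage("diffexpr", [outdir / "significance.tsv"])
            return sig

        sig_genes = guard("diffexpr", _diffexpr)

    # ---- cluster ----------------------------------------------------------
    som = None
    if "cluster" not in config.skip:
        def _cluster():
            params = config.resolved("cluster")
            dendro = hier_cluster(expr, axis="samples")
            cut = dendro.cut(params["hier_similarity"])
            pd.DataFrame(
                sorted(cut.items()), columns=["sample", "cluster"]
            ).pipe(_write_tsv, outdir / "hier_samples.tsv")
            section = {"params": params,
                       "sample_clusters": {k: int(v) for k, v in cut.items()}}

            som_set = None
            n_cells = params["som_rows"] * params["som_cols"]
            pool = sig_genes if sig_genes else []
            if len(pool) >= n_cells:
                som_set = som_cluster(
                    expr.subset(pool),
                    rows=params["som_rows"],
                    cols=params["som_cols"],
                    n_iter=params["n_iter"],
                    seed=stage_seed(config.seed, "som"),
                    ci_level=params["ci_level"],
                    max_outside_frac=params["max_outside_frac"],
                )
                section["som"] = {
                    "shape": list(som_set.shape),
                    "members": {str(c): sorted(g) for c, g in som_set.members.items()},
                    "n_unassigned": len(som_set.unassigned),
                }
                (outdir / "som_clusters.json").write_text(
                    json.dumps(section["som"], indent=2, sort_keys=True, default=_json_default) + "\n",
                    encoding="utf-8",
                )
                files = [outdir / "hier_samples.tsv", outdir / "som_clusters.json"]
            else:
                section["som"] = None
                section["som_skipped_reason"] = (
                    f"{len(pool)} significant genes < {n_cells} SOM cells"
                )
                files = [outdir / "hier_samples.tsv"]
            report["clustering"] = section
            finish_stage("cluster", files)
            return som_set

        som = guard("cluster", _cluster)

    # ---- npnet ------------------------------------------------------------
    partition = None
    if "npnet" not in config.skip:
        def _npnet():
            params = config.resolved("npnet")
            reduced = reduce_network(network, expr, threshold=params["pcc_threshold"])
            _write_tsv(reduced.edges_frame(), outdir / "reduced_edges.tsv")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                part = find_modules(reduced, expr, max_anti_frac=params["max_anti_frac"])
            _write_tsv(part.modules, outdir / "modules.tsv")
            assignment = pd.DataFrame(
                sorted(part.assignment.items()), columns=["node", "module"]
            )
            _write_tsv(assignment, outdir / "module_assignment.tsv")
            hubs = classify_hubs(reduced, min_degree=params["min_hub_degree"], partition=part)
            _write_tsv(hubs, outdir / "hubs.tsv")
            nodes_df, tf_pairs = interface_core(part, reduced)
            _write_tsv(nodes_df, outdir / "interface_core.tsv")
            section = {
                "params": params,
                "counts": reduced.counts(),
                "n_skipped_constant": reduced.n_skipped_constant,
                "modules": part.modules.to_dict(orient="records"),
                "n_unclustered": len(part.unclustered),
                "n_hubs": int(len(hubs)),
                "n_party": int((hubs["hub_class"] == "party").sum()) if len(hubs) else 0,
                "n_date": int((hubs["hub_class"] == "date").sum()) if len(hubs) else 0,
                "tf_interface_pairs": tf_pairs.to_dict(orient="records"),
            }
            files = [outdir / n for n in (
                "reduced_edges.tsv", "modules.tsv", "module_assignment.tsv",
                "hubs.tsv", "interface_core.tsv")]
            if len(part.module_labels) >= 2:
                summary = inter_module_summary(part, expr)
                summary = summary.assign(mean_pcc=summary["mean_pcc"].round(10))
                _write_tsv(summary, outdir / "inter_module.tsv")
                section["inter_module"] = summary.to_dict(orient="records")
                files.append(outdir / "inter_module.tsv")
            else:
                section["inter_module"] = None
            report["np_network"] = section
            finish_stage("npnet", files)
            return part

        partition = guard("npnet", _npnet)

    # ---- enrich -----------------------------------------------------------
    if "enrich" not in config.skip:
        def _enrich():
            params = config.resolved("enrich")
            background = list(expr.gene_ids)
            section: dict = {"params": params, "hypergeometric": {}, "dp": {}}
            files = []
            if som is not None:
                for cell, genes in sorted(som.members.items()):
                    if not genes:
                        continue
                    table = hypergeom_enrich(genes, background, annotations,
                                             alpha=params["alpha"])
                    section["hypergeometric"][f"som_{cell}"] = table.head(5).to_dict(
                        orient="records"
                    )
                    _write_tsv(table, outdir / f"enrich_hyper_som{cell}.tsv")
                    files.append(outdir / f"enrich_hyper_som{cell}.tsv")
            if partition is not None:
                for module in partition.module_labels:
                    table = dp_enrich(partition.members(module), annotations,
                                      formula=params["dp_formula"])
                    section["dp"][module] = table.head(10).to_dict(orient="records")
                    _write_tsv(table, outdir / f"enrich_dp_{module}.tsv")
                    files.append(outdir / f"enrich_dp_{module}.tsv")
            report["enrichment"] = section
            finish_stage("enrich", files)

        guard("enrich", _enrich)

    report_path = outdir / "report.json"
    report_path.write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n", encoding="utf-8"
    )
    artifacts[report_path.name] = _sha256(report_path)
    write_manifest()
    return report
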