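"""End-to-end orchestration: simulate/load -> filter -> DE -> network ->
modules -> survival -> enrichment, with a machine-readable run report.

A run is driven by a :class:`PipelineConfig` (loadable from YAML).  Inputs
come either from a bundled synthetic-cohort simulation (``simulate``
section) or from files on disk; every stage writes its intermediate
artifact in the same format the standalone commands consume, so any stage
can be rerun alone.  One global seed deterministically derives all stage
seeds, and a rerun with the same config and seed reproduces every output
bit-identically.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .synthetic import SimulationConfig, simulate_cohort, write_fixtures
from .de import DeConfig, run_de, de_gene_sets
from .network import build_network, filter_ago, degree_summary, write_edge_list
from .modules import ModuleParams, detect_modules, modules_to_jsonable
from .survival import stratify_module, module_expression_test
from .enrichment import ora_collection, ssgsea_scores, module_pathway_correlation, compare_group_scores

logger = logging.getLogger("cernet")

__version__ = "0.1.0"

_STAGES = ("simulate", "de", "network", "modules", "survival", "enrichment")


@dataclass
class PipelineConfig:
    out_dir: str = "cernet_run"
    seed: int = 0
    simulate: SimulationConfig | None = field(default_factory=SimulationConfig)
    # file inputs, used when simulate is None
    expression_mrna: str | None = None
    expression_lncrna: str | None = None
    expression_mirna: str | None = None
    samples: str | None = None
    interactions: str | None = None
    gene_sets: str | None = None
    de: DeConfig = field(default_factory=DeConfig)
    r_threshold: float = 0.3
    p_threshold: float = 0.01
    min_ago_sites: int = 1
    require_negative: bool = False
    modules: ModuleParams = field(default_factory=ModuleParams)
    ssgsea_tau: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "simulate":
                cfg.simulate = SimulationConfig(**value) if value is not None else None
            elif key == "de":
                cfg.de = DeConfig(**value)
            elif key == "modules":
                cfg.modules = ModuleParams(**value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown pipeline config key {key!r}")
        return cfg

    def validate_inputs(self) -> None:
        if self.simulate is not None:
            self.simulate.validate()
            return
        required = (
            "expression_mrna",
            "expression_lncrna",
            "expression_mirna",
            "samples",
            "interactions",
            "gene_sets",
        )
        for name in required:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"pipeline config missing input path {name!r}")
            if not Path(value).exists():
                raise FileNotFoundError(f"{name}: no such file {value!r}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    ss = np.random.SeedSequence([global_seed, sum(ord(c) for c in stage), len(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run report (also written as JSON)."""
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {
        "version": __version__,
        "config": _config_echo(config),
        "stages": {},
    }
    stage = "setup"
    try:
        # ------------------------------------------------ inputs
        stage = "simulate"
        if config.simulate is not None:
            sim = SimulationConfig(**{**asdict(config.simulate), "seed": stage_seed(config.seed, "simulate")})
            bundle, samples, catalog, gene_sets, truth = simulate_cohort(sim)
            write_fixtures(bundle, samples, catalog, gene_sets, truth, out / "fixtures")
            report["stages"]["simulate"] = {
                "n_genes": {c: int(m.shape[0]) for c, m in zip(("mRNA", "lncRNA", "miRNA"), (bundle.mrna, bundle.lncrna, bundle.mirna))},
                "n_samples": len(bundle.sample_ids),
                "n_interactions": int(len(catalog)),
                "n_gene_sets": len(gene_sets),
            }
        else:
            bundle = cio.ExpressionBundle(
                mrna=cio.read_expression_tsv(config.expression_mrna),
                lncrna=cio.read_expression_tsv(config.expression_lncrna),
                mirna=cio.read_expression_tsv(config.expression_mirna),
            )
            samples = cio.read_samples(config.samples)
            catalog = cio.read_interactions(config.interactions)
            gene_sets = cio.read_gmt(config.gene_sets)
            truth = None
            report["stages"]["simulate"] = {"skipped": True}

        # ------------------------------------------------ DE per class
        stage = "de"
        de_by_class: dict[str, pd.DataFrame] = {}
        de_counts = {}
        for cls, matrix in (("mRNA", bundle.mrna), ("lncRNA", bundle.lncrna), ("miRNA", bundle.mirna)):
            table = run_de(matrix, samples, config.de)
            de_by_class[cls] = table
            table.to_csv(out / f"de_{cls.lower()}.tsv", sep="\t", index=False)
            de_counts[cls] = {
                "tested": int(len(table)),
                "filtered_out": int(matrix.shape[0] - len(table)),
                "up": int((table["direction"] == "up").sum()),
                "down": int((table["direction"] == "down").sum()),
            }
        report["stages"]["de"] = de_counts

        # ------------------------------------------------ network
        stage = "network"
        cat_ago = filter_ago(catalog, config.min_ago_sites)
        net = build_network(
            de_by_class,
            cat_ago,
            bundle,
            r_threshold=config.r_threshold,
            p_threshold=config.p_threshold,
            require_negative=config.require_negative,
            pseudocount=config.de.pseudocount,
        )
        write_edge_list(net, out / "network_edges.tsv")
        net_report = {
            "catalog_pairs": int(len(catalog)),
            "after_ago_filter": int(len(cat_ago)),
            "edges": net.n_edges,
            "nodes": net.n_nodes,
            "class_counts": net.class_counts(),
        }
        if net.n_edges:
            frac_lt5, frac_gt10, hist = degree_summary(net)
            net_report["frac_degree_lt5"] = frac_lt5
            net_report["frac_degree_gt10"] = frac_gt10
            net_report["degree_histogram"] = {str(k): v for k, v in sorted(hist.items())}
        report["stages"]["network"] = net_report

        # ------------------------------------------------ modules
        stage = "modules"
        mods = detect_modules(net, config.modules)
        cio.write_json(modules_to_jsonable(mods), out / "modules.json")
        report["stages"]["modules"] = {
            "count": len(mods),
            "summaries": [m.summary() for m in mods],
        }

        # ------------------------------------------------ survival
        stage = "survival"
        surv_rows = []
        seed_surv = stage_seed(config.seed, "survival")
        for m in mods:
            strat = stratify_module(m, bundle, samples, seed=seed_surv, pseudocount=config.de.pseudocount)
            u, p_rs, direction = module_expression_test(m, bundle, samples, pseudocount=config.de.pseudocount)
            surv_rows.append(
                {
                    "module_id": m.module_id,
                    "n_group1": strat.group_sizes[1],
                    "n_group2": strat.group_sizes[2],
                    "chi_square": strat.chi_square,
                    "p_logrank": strat.p_logrank,
                    "ranksum_u": u,
                    "p_ranksum": p_rs,
                    "direction": direction,
                }
            )
        surv_table = pd.DataFrame(
            surv_rows,
            columns=[
                "module_id", "n_group1", "n_group2", "chi_square",
                "p_logrank", "ranksum_u", "p_ranksum", "direction",
            ],
        )
        surv_table.to_csv(out / "survival.tsv", sep="\t", index=False)
        report["stages"]["survival"] = surv_table.to_dict(orient="records")

        # ------------------------------------------------ enrichment
        stage = "enrichment"
        de_mrna = de_gene_sets(de_by_class["mRNA"])["all"]
        universe = set(de_by_class["mRNA"]["gene_id"])
        ora = ora_collection(de_mrna, gene_sets, universe)
        ora.to_csv(out / "ora_de_mrna.tsv", sep="\t", index=False)
        scores = ssgsea_scores(bundle.mrna, gene_sets, tau=config.ssgsea_tau)
        scores.to_csv(out / "ssgsea_scores.tsv", sep="\t", index_label="set_name")
        mod_corr = {}
        for m in mods:
            nodes = sorted(m.nodes)
            log_expr = np.log2(bundle.stacked().loc[nodes] + config.de.pseudocount)
            mod_score = log_expr.mean(axis=0)
            tab = module_pathway_correlation(mod_score, scores)
            tab.to_csv(out / f"module_{m.module_id}_pathway_corr.tsv", sep="\t", index=False)
            mod_corr[m.module_id] = tab.to_dict(orient="records")
        cond_labels = samples.set_index("sample_id")["condition"]
        group_cmp = compare_group_scores(scores, cond_labels)
        group_cmp.to_csv(out / "ssgsea_tumor_vs_normal.tsv", sep="\t", index=False)
        report["stages"]["enrichment"] = {
            "ora_top": ora.nsmallest(5, "p").to_dict(orient="records"),
            "module_pathway_correlation": mod_corr,
            "n_sets_scored": int(scores.shape[0]),
        }

        stage = "report"
        _check_consistency(report)
        cio.write_json(report, out / "report.json")
        # wall time stays out of the report so reruns are bit-identical
        logger.info("pipeline finished in %.2fs", time.time() - t0)
        return report
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    return echo


def _check_consistency(report: dict) -> None:
    """Internal cross-checks before the report is written."""
    for cls, counts in report["stages"]["de"].items():
        if counts["up"] + counts["down"] > counts["tested"]:
            raise AssertionError(f"DE counts inconsistent for {cls}")
    net = report["stages"]["network"]
    if net["edges"]:
        if sum(net["class_counts"].values()) != net["nodes"]:
            raise AssertionError("network node count != sum of class counts")
    for summary in report["stages"]["modules"]["summaries"]:
        if summary["n_mrna"] + summary["n_lncrna"] + summary["n_mirna"] < 2:
            raise AssertionError("degenerate module in report")
    if len(report["stages"]["survival"]) != report["stages"]["modules"]["count"]:
        raise AssertionError("survival rows != module count")
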