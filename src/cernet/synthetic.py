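"""Synthetic tumor-vs-normal cohort generator with planted ground truth.

Emulates the statistical structure of a bulk-RNA cancer cohort in which a
dysregulated lncRNA-miRNA-mRNA network is to be recovered:

* log-normal abundance per gene (Gaussian on the log2 scale), with a
  per-class baseline so mRNA / lncRNA / miRNA live on realistic,
  different dynamic ranges;
* a planted fraction of differentially expressed (DE) genes per class with
  configurable log2 fold change between tumor and normal;
* planted miRNA regulons: each regulon miRNA shares a latent factor with its
  targets with opposite loadings, so miRNA and target are anti-correlated at
  a configurable strength (the miRNA-repression signature the network
  filter is meant to detect);
* star-shaped tri-class modules built from pairs of regulons joined by a
  bridge target; module RNAs are overexpressed in tumors and the first
  module's expression drives an exponential survival hazard;
* decoy miRNA-target interactions between genes with independent noise,
  standing in for the predicted-but-unsupported pairs a public catalog
  contains;
* gene sets enriched in planted DE genes alongside random background sets.

Everything is driven by one integer seed: the same configuration and seed
reproduce every output bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (
    ExpressionBundle,
    GeneAnnotation,
    GeneSetCollection,
    read_expression_tsv,
    write_expression_tsv,
    write_gtf,
    write_gmt,
    write_interactions,
    write_samples,
    write_json,
    INTERACTION_COLUMNS,
)

# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Counts are genes per RNA class and samples per condition; effect sizes
    are in log2 units; ``regulon_strength`` is the target absolute Pearson
    correlation (within condition) between a regulon miRNA and its targets;
    ``hazard_beta`` is the log-hazard increase per standard deviation of the
    prognostic module score; ``baseline_scale`` is the baseline mean
    survival time in days.
    """

    n_mrna: int = 500
    n_lncrna: int = 200
    n_mirna: int = 100
    n_tumor: int = 60
    n_normal: int = 20
    frac_de: float = 0.15
    de_log2fc_mean: float = 2.0
    de_log2fc_sd: float = 0.25
    n_regulons: int = 10
    regulon_strength: float = 0.8
    mrna_targets_per_regulon: int = 5
    lncrna_targets_per_regulon: int = 2
    n_decoy_interactions: int = 200
    n_modules: int = 2
    regulons_per_module: int = 2
    hazard_beta: float = 1.5
    censor_rate: float = 0.3
    baseline_scale: float = 1000.0
    noise_sd: float = 0.5
    n_background_sets: int = 8
    gene_set_size: int = 25
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_mrna": self.n_mrna,
            "n_lncrna": self.n_lncrna,
            "n_mirna": self.n_mirna,
            "n_tumor": self.n_tumor,
            "n_normal": self.n_normal,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0 (got {v})")
        if self.n_tumor < 3 or self.n_normal < 3:
            raise ValueError("need >= 3 samples per condition for the t-test")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if not 0.0 < self.regulon_strength < 1.0:
            raise ValueError("regulon_strength must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for cls, n in (("mrna", self.n_mrna), ("lncrna", self.n_lncrna), ("mirna", self.n_mirna)):
            if int(round(self.frac_de * n)) < 1:
                raise ValueError(f"frac_de * n_{cls} < 1: nothing to plant")
        if self.n_regulons > int(round(self.frac_de * self.n_mirna)):
            raise ValueError("n_regulons exceeds the number of planted DE miRNAs")
        if self.n_regulons * self.mrna_targets_per_regulon > int(round(self.frac_de * self.n_mrna)):
            raise ValueError("not enough planted DE mRNAs for the requested regulons")
        if self.n_regulons * self.lncrna_targets_per_regulon > int(round(self.frac_de * self.n_lncrna)):
            raise ValueError("not enough planted DE lncRNAs for the requested regulons")
        if self.n_modules * self.regulons_per_module > self.n_regulons:
            raise ValueError("modules consume more regulons than exist")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort, the oracle for recovery tests."""

    de_genes_by_class: dict[str, dict[str, str]]  # class -> gene -> up/down
    true_edges: set[tuple[str, str]]
    planted_modules: list[set[str]]
    prognostic_module_index: int
    enriched_sets: list[str]
    prognostic_score_by_sample: dict[str, float]

    def de_gene_ids(self, rna_class: str) -> set[str]:
        return set(self.de_genes_by_class[rna_class])

    def all_de_gene_ids(self) -> set[str]:
        out: set[str] = set()
        for d in self.de_genes_by_class.values():
            out |= set(d)
        return out

    def to_jsonable(self) -> dict:
        return {
            "de_genes_by_class": self.de_genes_by_class,
            "true_edges": sorted(map(list, self.true_edges)),
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "prognostic_module_index": self.prognostic_module_index,
            "enriched_sets": list(self.enriched_sets),
            "prognostic_score_by_sample": self.prognostic_score_by_sample,
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "SimulationTruth":
        return cls(
            de_genes_by_class=obj["de_genes_by_class"],
            true_edges={tuple(e) for e in obj["true_edges"]},
            planted_modules=[set(m) for m in obj["planted_modules"]],
            prognostic_module_index=obj["prognostic_module_index"],
            enriched_sets=list(obj["enriched_sets"]),
            prognostic_score_by_sample=obj["prognostic_score_by_sample"],
        )


# Baseline mean log2 abundance per class; spread makes dynamic range realistic.
_BASELINE_MEAN = {"mRNA": 5.0, "lncRNA": 3.0, "miRNA": 6.0}
_BASELINE_SD = 1.5


def _censor_horizon(censor_rate: float, baseline_scale: float) -> float:
    """Upper bound of the uniform censoring window.

    For T ~ Exp(1/s) and C ~ U(0, k*s), P(C < T) = (1 - exp(-k))/k; solve
    for k so the expected censoring fraction under the baseline hazard
    matches ``censor_rate``.
    """
    if censor_rate <= 0:
        return np.inf
    k = brentq(lambda k: (1 - np.exp(-k)) / k - censor_rate, 1e-9, 1e6)
    return k * baseline_scale


def simulate_cohort(config: SimulationConfig):
    """Generate one synthetic cohort.

    Returns ``(bundle, samples, catalog, gene_sets, truth)`` where bundle is
    an :class:`ExpressionBundle`, samples the metadata table, catalog the
    miRNA-target interaction table (planted regulon edges with AGO support
    plus decoys), gene_sets a :class:`GeneSetCollection`, and truth the
    planted signal.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = {
        "mRNA": [f"MG{i:04d}" for i in range(config.n_mrna)],
        "lncRNA": [f"LNC{i:04d}" for i in range(config.n_lncrna)],
        "miRNA": [f"MIR{i:04d}" for i in range(config.n_mirna)],
    }
    n_genes = {c: len(g) for c, g in gene_ids.items()}
    sample_ids = [f"TUMOR_{i:03d}" for i in range(config.n_tumor)] + [
        f"NORMAL_{i:03d}" for i in range(config.n_normal)
    ]
    is_tumor = np.array([1.0] * config.n_tumor + [0.0] * config.n_normal)
    n_samples = len(sample_ids)

    # --- choose planted DE genes per class ---------------------------------
    de_index: dict[str, np.ndarray] = {}
    for cls in ("mRNA", "lncRNA", "miRNA"):
        k = int(round(config.frac_de * n_genes[cls]))
        de_index[cls] = np.sort(rng.choice(n_genes[cls], size=k, replace=False))

    # --- regulon / module layout ------------------------------------------
    # Regulons are drawn from the planted-DE pools so every planted edge
    # joins DE genes; the first regulons_per_module * n_modules regulons are
    # grouped into modules sharing one latent factor each.
    de_mirna = list(de_index["miRNA"])
    de_mrna = list(de_index["mRNA"])
    de_lncrna = list(de_index["lncRNA"])
    regulon_mirna = de_mirna[: config.n_regulons]
    mt, lt = config.mrna_targets_per_regulon, config.lncrna_targets_per_regulon
    regulon_mrna = [de_mrna[i * mt : (i + 1) * mt] for i in range(config.n_regulons)]
    regulon_lncrna = [de_lncrna[i * lt : (i + 1) * lt] for i in range(config.n_regulons)]

    in_module = config.n_modules * config.regulons_per_module
    # factor index per regulon: module regulons share their module's factor
    factor_of_regulon = [
        (r // config.regulons_per_module) if r < in_module else (config.n_modules + r - in_module)
        for r in range(config.n_regulons)
    ]
    n_factors = config.n_modules + (config.n_regulons - in_module)

    # loading magnitude giving within-condition |r| = regulon_strength
    rho = config.regulon_strength
    a = config.noise_sd * np.sqrt(rho / (1.0 - rho))

    # --- per-gene effect sizes and loadings --------------------------------
    sign = {cls: np.zeros(n_genes[cls]) for cls in gene_ids}  # DE direction
    loading = {cls: np.zeros((n_genes[cls], n_factors)) for cls in gene_ids}
    for cls in gene_ids:
        s = rng.choice([-1.0, 1.0], size=len(de_index[cls]))
        sign[cls][de_index[cls]] = s
    for r in range(config.n_regulons):
        f = factor_of_regulon[r]
        module_regulon = r < in_module
        # module regulons: targets up / miRNA down (modules overexpressed in
        # tumor); standalone regulons: miRNA up / targets down.
        mirna_sign, target_sign = (-1.0, 1.0) if module_regulon else (1.0, -1.0)
        sign["miRNA"][regulon_mirna[r]] = mirna_sign
        loading["miRNA"][regulon_mirna[r], f] = a
        for idx in regulon_mrna[r]:
            sign["mRNA"][idx] = target_sign
            loading["mRNA"][idx, f] = -a
        for idx in regulon_lncrna[r]:
            sign["lncRNA"][idx] = target_sign
            loading["lncRNA"][idx, f] = -a

    delta = {}
    for cls in gene_ids:
        mag = np.abs(rng.normal(config.de_log2fc_mean, config.de_log2fc_sd, n_genes[cls]))
        delta[cls] = sign[cls] * mag

    # --- expression --------------------------------------------------------
    factors = rng.standard_normal((n_factors, n_samples))
    matrices: dict[str, pd.DataFrame] = {}
    for cls in ("mRNA", "lncRNA", "miRNA"):
        base = rng.normal(_BASELINE_MEAN[cls], _BASELINE_SD, n_genes[cls])
        eps = rng.normal(0.0, config.noise_sd, (n_genes[cls], n_samples))
        log2x = (
            base[:, None]
            + delta[cls][:, None] * is_tumor[None, :]
            + loading[cls] @ factors
            + eps
        )
        matrices[cls] = pd.DataFrame(
            np.exp2(log2x), index=gene_ids[cls], columns=sample_ids
        )
    bundle = ExpressionBundle(
        mrna=matrices["mRNA"], lncrna=matrices["lncRNA"], mirna=matrices["miRNA"]
    )

    # --- interaction catalog: planted edges + bridge edges + decoys --------
    rows: list[tuple[str, str, str, int]] = []
    true_edges: set[tuple[str, str]] = set()

    def add_edge(mi_idx: int, tg_idx: int, tg_cls: str, sites: int) -> None:
        mi = gene_ids["miRNA"][mi_idx]
        tg = gene_ids[tg_cls][tg_idx]
        rows.append((mi, tg, tg_cls, sites))
        true_edges.add((mi, tg))

    for r in range(config.n_regulons):
        for idx in regulon_mrna[r]:
            add_edge(regulon_mirna[r], idx, "mRNA", int(rng.integers(1, 6)))
        for idx in regulon_lncrna[r]:
            add_edge(regulon_mirna[r], idx, "lncRNA", int(rng.integers(1, 6)))
    # bridge: the second regulon's miRNA also targets the first regulon's
    # first mRNA, making each module one connected tri-class cluster
    planted_modules: list[set[str]] = []
    for m in range(config.n_modules):
        regs = list(range(m * config.regulons_per_module, (m + 1) * config.regulons_per_module))
        nodes: set[str] = set()
        for r in regs:
            nodes.add(gene_ids["miRNA"][regulon_mirna[r]])
            nodes |= {gene_ids["mRNA"][i] for i in regulon_mrna[r]}
            nodes |= {gene_ids["lncRNA"][i] for i in regulon_lncrna[r]}
        for r in regs[1:]:
            add_edge(regulon_mirna[r], regulon_mrna[regs[0]][0], "mRNA", int(rng.integers(1, 6)))
        planted_modules.append(nodes)

    # decoys: uniform random miRNA-target pairs not planted; independent
    # noise (no shared factor), AGO evidence mimicking a predicted pair
    existing = set(true_edges)
    n_decoys = 0
    while n_decoys < config.n_decoy_interactions:
        mi_idx = int(rng.integers(n_genes["miRNA"]))
        tg_cls = "mRNA" if rng.random() < config.n_mrna / (config.n_mrna + config.n_lncrna) else "lncRNA"
        tg_idx = int(rng.integers(n_genes[tg_cls]))
        mi = gene_ids["miRNA"][mi_idx]
        tg = gene_ids[tg_cls][tg_idx]
        if (mi, tg) in existing:
            continue
        existing.add((mi, tg))
        rows.append((mi, tg, tg_cls, int(rng.integers(0, 4))))
        n_decoys += 1

    catalog = pd.DataFrame(rows, columns=INTERACTION_COLUMNS)

    # --- survival ----------------------------------------------------------
    prognostic = planted_modules[0]
    mod_expr = bundle.stacked().loc[sorted(prognostic)]
    log2_mod = np.log2(mod_expr.to_numpy() + 1e-9)
    score = log2_mod.mean(axis=0)[: config.n_tumor]  # tumor samples only
    z = (score - score.mean()) / score.std(ddof=0)
    t_true = rng.exponential(config.baseline_scale * np.exp(-config.hazard_beta * z))
    horizon = _censor_horizon(config.censor_rate, config.baseline_scale)
    if np.isfinite(horizon):
        c_time = rng.uniform(0.0, horizon, size=config.n_tumor)
    else:
        c_time = np.full(config.n_tumor, np.inf)
    observed = np.minimum(t_true, c_time)
    event = (t_true <= c_time).astype(int)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
            "survival_days": np.concatenate(
                [np.round(observed, 2), np.full(config.n_normal, np.nan)]
            ),
            "event": np.concatenate(
                [event.astype(float), np.full(config.n_normal, np.nan)]
            ),
        }
    )

    # --- gene sets ---------------------------------------------------------
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    all_de_mrna = {gene_ids["mRNA"][i] for i in de_index["mRNA"]}
    enriched_names: list[str] = []
    for m, nodes in enumerate(planted_modules):
        name = f"PLANTED_SET_M{m + 1}"
        members = {g for g in nodes if g.startswith("MG")}
        pool = sorted(all_de_mrna - members)
        extra = rng.choice(pool, size=max(0, config.gene_set_size - len(members)), replace=False)
        sets[name] = members | set(extra)
        descriptions[name] = f"planted DE-enriched set around module {m + 1}"
        enriched_names.append(name)
    for b in range(config.n_background_sets):
        name = f"RANDOM_SET_{b + 1}"
        members = rng.choice(gene_ids["mRNA"], size=config.gene_set_size, replace=False)
        sets[name] = set(members)
        descriptions[name] = "random background set"
    gene_sets = GeneSetCollection(sets=sets, descriptions=descriptions)

    # --- truth -------------------------------------------------------------
    dir_name = {1.0: "up", -1.0: "down"}
    de_genes_by_class = {
        cls: {
            gene_ids[cls][i]: dir_name[sign[cls][i]]
            for i in de_index[cls]
        }
        for cls in ("mRNA", "lncRNA", "miRNA")
    }
    truth = SimulationTruth(
        de_genes_by_class=de_genes_by_class,
        true_edges=true_edges,
        planted_modules=planted_modules,
        prognostic_module_index=0,
        enriched_sets=enriched_names,
        prognostic_score_by_sample={
            sample_ids[i]: float(z[i]) for i in range(config.n_tumor)
        },
    )
    return bundle, samples, catalog, gene_sets, truth


# ---------------------------------------------------------------------------
# Fixture output


def make_annotation(bundle: ExpressionBundle) -> GeneAnnotation:
    """GENCODE-style annotation matching the bundle's gene ids."""
    biotype: dict[str, str] = {}
    biotype.update({g: "protein_coding" for g in bundle.mrna.index})
    # mix umbrella and legacy lncRNA biotypes so classification is exercised
    lnc_bts = ["lncRNA", "lincRNA", "antisense", "processed_transcript"]
    for i, g in enumerate(bundle.lncrna.index):
        biotype[g] = lnc_bts[i % len(lnc_bts)]
    biotype.update({g: "miRNA" for g in bundle.mirna.index})
    return GeneAnnotation(biotype=biotype)


def write_fixtures(
    bundle: ExpressionBundle,
    samples: pd.DataFrame,
    catalog: pd.DataFrame,
    gene_sets: GeneSetCollection,
    truth: SimulationTruth,
    dir_path: str | Path,
) -> dict:
    """Write the full cohort to ``dir_path`` as plain-text files.

    The manifest's ``files`` entry lists the seven pipeline input files
    (three expression TSVs, annotation GTF, sample TSV, interaction TSV,
    gene-set GMT); the truth JSON is recorded separately under ``truth``
    since it is an oracle, not a pipeline input.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "expression_mrna": "expression_mrna.tsv",
        "expression_lncrna": "expression_lncrna.tsv",
        "expression_mirna": "expression_mirna.tsv",
        "annotation": "annotation.gtf",
        "samples": "samples.tsv",
        "interactions": "interactions.tsv",
        "gene_sets": "gene_sets.gmt",
    }
    write_expression_tsv(bundle.mrna, out / files["expression_mrna"])
    write_expression_tsv(bundle.lncrna, out / files["expression_lncrna"])
    write_expression_tsv(bundle.mirna, out / files["expression_mirna"])
    write_gtf(make_annotation(bundle), out / files["annotation"])
    write_samples(samples, out / files["samples"])
    write_interactions(catalog, out / files["interactions"])
    write_gmt(gene_sets, out / files["gene_sets"])
    write_json(truth.to_jsonable(), out / "truth.json")
    manifest = {"files": files, "truth": "truth.json", "dir": str(out)}
    write_json(manifest, out / "manifest.json")
    return manifest


def read_fixture_bundle(dir_path: str | Path) -> ExpressionBundle:
    """Read the three per-class expression TSVs written by write_fixtures."""
    out = Path(dir_path)
    return ExpressionBundle(
        mrna=read_expression_tsv(out / "expression_mrna.tsv"),
        lncrna=read_expression_tsv(out / "expression_lncrna.tsv"),
        mirna=read_expression_tsv(out / "expression_mirna.tsv"),
    )
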