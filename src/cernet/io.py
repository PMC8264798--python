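"""Readers and writers for the standard formats the pipeline consumes.

Expression tables are plain TSV (genes as rows, samples as columns), gene
annotation is GTF with GENCODE biotypes, miRNA-target interactions are a
four-column TSV, gene sets are GMT, and sample metadata (condition plus
survival) is TSV.  Every reader validates its input and raises on malformed
records rather than silently coercing them.

Genes are partitioned into the three RNA classes used throughout the
pipeline -- mRNA, lncRNA and miRNA -- purely by GENCODE biotype.  The lncRNA
vocabulary accepts both the umbrella biotype ``lncRNA`` (GENCODE >= v31) and
the older subtype names (``lincRNA``, ``antisense``, ...), since public
annotation releases mix the two.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("cernet")

# ---------------------------------------------------------------------------
# Biotype vocabulary

#: GENCODE biotypes classified as long non-coding RNA.
LNCRNA_BIOTYPES = frozenset(
    {
        "antisense",
        "lincRNA",
        "lncRNA",
        "processed_transcript",
        "sense_intronic",
        "sense_overlapping",
        "TEC",
    }
)

MRNA_BIOTYPES = frozenset({"protein_coding"})
MIRNA_BIOTYPES = frozenset({"miRNA"})

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")


def rna_class_of(biotype: str) -> str:
    """Map a GENCODE biotype to one of mRNA / lncRNA / miRNA / other."""
    if biotype in MRNA_BIOTYPES:
        return "mRNA"
    if biotype in LNCRNA_BIOTYPES:
        return "lncRNA"
    if biotype in MIRNA_BIOTYPES:
        return "miRNA"
    return "other"


# ---------------------------------------------------------------------------
# Containers


@dataclass
class GeneAnnotation:
    """gene_id -> (biotype, rna_class) mapping derived from a GTF."""

    biotype: dict[str, str] = field(default_factory=dict)

    def rna_class(self, gene_id: str) -> str:
        return rna_class_of(self.biotype[gene_id])

    def __len__(self) -> int:
        return len(self.biotype)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.biotype


@dataclass
class ExpressionBundle:
    """The three per-class expression matrices sharing one sample set.

    Each matrix is a genes x samples DataFrame of non-negative abundances.
    """

    mrna: pd.DataFrame
    lncrna: pd.DataFrame
    mirna: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.mrna.columns)
        for name, m in (("lncrna", self.lncrna), ("mirna", self.mirna)):
            if list(m.columns) != cols:
                raise ValueError(f"sample columns of {name} differ from mrna")
        for name, m in self.items():
            validate_expression(m, name=name)

    def items(self):
        return [("mrna", self.mrna), ("lncrna", self.lncrna), ("mirna", self.mirna)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mrna.columns)

    def matrix_for_class(self, rna_class: str) -> pd.DataFrame:
        return {"mRNA": self.mrna, "lncRNA": self.lncrna, "miRNA": self.mirna}[rna_class]

    def class_of_gene(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for cls, m in zip(RNA_CLASSES, (self.mrna, self.lncrna, self.mirna)):
            out.update({g: cls for g in m.index})
        return out

    def stacked(self) -> pd.DataFrame:
        """All three matrices stacked row-wise (gene ids stay unique)."""
        return pd.concat([self.mrna, self.lncrna, self.mirna], axis=0)


def validate_expression(matrix: pd.DataFrame, name: str = "expression") -> None:
    """Enforce the expression-matrix invariants (unique ids, finite, >= 0)."""
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"{name}: duplicate gene id {dup!r}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValueError(f"{name}: duplicate sample id {dup!r}")
    values = matrix.to_numpy()
    if values.size and not np.isfinite(values).all():
        raise ValueError(f"{name}: non-finite values present")
    if values.size and (values < 0).any():
        raise ValueError(f"{name}: negative abundance values present")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty member sets."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# GTF


_GTF_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def classify_biotypes(gtf_path: str | Path) -> GeneAnnotation:
    """Read gene-level biotypes from a GTF file.

    Only ``gene`` feature lines are used.  The biotype is taken from the
    ``gene_type`` attribute with ``gene_biotype`` as a fallback.  A gene line
    missing ``gene_id`` or a biotype attribute raises a parse error naming
    the offending line number.
    """
    biotype: dict[str, str] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gtf_path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{gtf_path}:{lineno}: missing gene_id attribute")
            bt = attrs.get("gene_type", attrs.get("gene_biotype"))
            if bt is None:
                raise ValueError(
                    f"{gtf_path}:{lineno}: missing gene_type/gene_biotype attribute"
                )
            biotype[gene_id] = bt
    return GeneAnnotation(biotype=biotype)


def write_gtf(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write minimal gene-line GTF carrying gene_id and gene_type."""
    with open(path, "w") as fh:
        for i, (gene_id, bt) in enumerate(annotation.biotype.items()):
            start = 1000 * i + 1
            attrs = f'gene_id "{gene_id}"; gene_type "{bt}";'
            fh.write(
                f"chr1\tcernet\tgene\t{start}\t{start + 999}\t.\t+\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Expression TSV


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read one genes x samples TSV (column 1 = gene id, row 1 = sample ids)."""
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty expression file") from exc
    if matrix.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    nonnum = matrix.columns[[not pd.api.types.is_numeric_dtype(d) for d in matrix.dtypes]]
    if len(nonnum):
        raise ValueError(f"{path}: non-numeric values in column {nonnum[0]!r}")
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    matrix.index.name = None
    matrix.columns.name = None
    validate_expression(matrix, name=str(path))
    return matrix


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def load_expression(tsv_path: str | Path, annotation: GeneAnnotation) -> ExpressionBundle:
    """Read one combined expression TSV and partition genes by RNA class.

    Genes classified ``other`` (or absent from the annotation) are dropped
    with a logged count; sample order is preserved and identical across the
    three class matrices.
    """
    matrix = read_expression_tsv(tsv_path)
    by_class: dict[str, list[str]] = {c: [] for c in RNA_CLASSES}
    dropped = 0
    for gene_id in matrix.index:
        cls = rna_class_of(annotation.biotype.get(gene_id, "")) if gene_id in annotation else "other"
        if cls == "other":
            dropped += 1
        else:
            by_class[cls].append(gene_id)
    if dropped:
        logger.info("load_expression: dropped %d genes with class 'other'", dropped)
    return ExpressionBundle(
        mrna=matrix.loc[by_class["mRNA"]],
        lncrna=matrix.loc[by_class["lncRNA"]],
        mirna=matrix.loc[by_class["miRNA"]],
    )


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# Interaction catalog TSV

INTERACTION_COLUMNS = ["mirna_id", "target_id", "target_class", "ago_sites"]


def read_interactions(path: str | Path) -> pd.DataFrame:
    """Read the miRNA-target catalog TSV.

    Columns: mirna_id, target_id, target_class (mRNA|lncRNA), ago_sites
    (integer >= 0, the number of AGO CLIP binding sites supporting the pair).
    """
    cat = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "target_id": str})
    missing = [c for c in INTERACTION_COLUMNS if c not in cat.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return validate_interactions(cat[INTERACTION_COLUMNS].copy(), name=str(path))


def validate_interactions(cat: pd.DataFrame, name: str = "interactions") -> pd.DataFrame:
    bad_class = set(cat["target_class"]) - {"mRNA", "lncRNA"}
    if bad_class:
        raise ValueError(f"{name}: unknown target_class values {sorted(bad_class)}")
    sites = pd.to_numeric(cat["ago_sites"], errors="coerce")
    if sites.isna().any() or (sites < 0).any() or (sites != sites.astype(int)).any():
        raise ValueError(f"{name}: ago_sites must be non-negative integers")
    cat["ago_sites"] = sites.astype(int)
    if cat.duplicated(["mirna_id", "target_id"]).any():
        raise ValueError(f"{name}: duplicate (mirna_id, target_id) pairs")
    return cat


def write_interactions(cat: pd.DataFrame, path: str | Path) -> None:
    cat[INTERACTION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample metadata TSV

SAMPLE_COLUMNS = ["sample_id", "condition", "survival_days", "event"]


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read the sample table: sample_id, condition, survival_days, event.

    Condition labels are case-normalized to ``tumor`` / ``normal``; survival
    fields may be missing (enforced only when survival analysis runs).
    """
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return validate_samples(table[SAMPLE_COLUMNS].copy(), name=str(path))


def validate_samples(table: pd.DataFrame, name: str = "samples") -> pd.DataFrame:
    if table["sample_id"].duplicated().any():
        raise ValueError(f"{name}: duplicate sample ids")
    cond = table["condition"].astype(str).str.lower()
    unknown = set(cond) - {"tumor", "normal"}
    if unknown:
        raise ValueError(f"{name}: unknown condition labels {sorted(unknown)}")
    table["condition"] = cond
    days = pd.to_numeric(table["survival_days"], errors="coerce")
    if (days.dropna() < 0).any():
        raise ValueError(f"{name}: negative survival_days")
    table["survival_days"] = days
    ev = pd.to_numeric(table["event"], errors="coerce")
    bad = ev.dropna()[~ev.dropna().isin([0, 1])]
    if len(bad):
        raise ValueError(f"{name}: event flags must be 0 or 1")
    table["event"] = ev
    return table


def write_samples(table: pd.DataFrame, path: str | Path) -> None:
    table[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# JSON helpers (truth files, reports)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
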