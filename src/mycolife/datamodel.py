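"""Core data structures and file I/O for the pipeline.

Every table is tab-separated with a header row; the first column is the
row identifier.  Trees are standard Newick with branch lengths; internal
nodes without labels receive deterministic names ``N1..Nk`` in preorder so
that ancestral reconstructions are addressable.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

LIFESTYLES = ("MyM", "SAP", "EF", "PPF", "ECM", "ERM", "OMF")
ANNOTATION_CATEGORIES = ("CAZyme", "protease", "lipase", "SSP", "other")
COMPARTMENTS = ("root", "soil", "leaf")

ANNOTATION_COLUMNS = ["category", "subfamily", "secreted", "pcwde", "fcwde"]


class ValidationError(ValueError):
    """A dataset violates one of the documented invariants."""


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """Rooted tree with named tips and non-negative branch lengths.

    Wraps a :class:`dendropy.Tree`.  Unlabeled internal nodes are named
    ``N1..Nk`` in preorder at construction time, so every node of the tree
    can be referred to by a stable identifier.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._name_internal_nodes()
        self._validate()

    def _name_internal_nodes(self) -> None:
        i = 0
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            i += 1
            if node.label is None or node.label == "":
                node.label = f"N{i}"

    def _validate(self) -> None:
        tips = self.tip_names
        if len(tips) != len(set(tips)):
            raise ValidationError("duplicate tip names in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError("negative branch length in tree")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=source, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
        return cls(tree)

    @classmethod
    def read(cls, path: str | os.PathLike) -> "Phylogeny":
        return cls.from_newick(Path(path).read_text())

    # -- accessors ---------------------------------------------------------
    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def node_names(self) -> list[str]:
        """All node names in preorder (internal labels then tip taxa)."""
        return [self.node_name(n) for n in self.tree.preorder_node_iter()]

    @property
    def internal_node_names(self) -> list[str]:
        return [n.label for n in self.tree.preorder_internal_node_iter()]

    @staticmethod
    def node_name(node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    def preorder_nodes(self):
        return list(self.tree.preorder_node_iter())

    def postorder_nodes(self):
        return list(self.tree.postorder_node_iter())

    def branches(self) -> list[tuple[str, str, float]]:
        """(parent, child, length) for every edge below the root, preorder."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            out.append((self.node_name(node.parent_node), self.node_name(node),
                        node.edge.length or 0.0))
        return out

    def patristic_distances(self, taxa: list[str] | None = None) -> pd.DataFrame:
        """Pairwise path-sum-of-branch-length distances between tips."""
        pdm = self.tree.phylogenetic_distance_matrix()
        names = taxa if taxa is not None else self.tip_names
        taxon_by_name = {t.label: t for t in self.tree.taxon_namespace}
        n = len(names)
        mat = np.zeros((n, n))
        for i, a in enumerate(names):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxon_by_name[a], taxon_by_name[names[j]])
                mat[i, j] = mat[j, i] = d
        return pd.DataFrame(mat, index=names, columns=names)

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True, real_value_format_specifier=".12g",
        )
        return s.strip() + "\n"

    def write(self, path: str | os.PathLike) -> None:
        Path(path).write_text(self.to_newick())


# ---------------------------------------------------------------------------
# Gene family matrix
# ---------------------------------------------------------------------------

@dataclass
class GeneFamilyMatrix:
    """Genomes x orthogroups copy-number matrix with per-family annotations.

    ``counts`` is indexed by genome id with one integer column per family.
    ``annotations`` is indexed by family id with columns
    category/subfamily/secreted/pcwde/fcwde; families missing from the
    table default to category ``other`` with all flags false.
    """

    counts: pd.DataFrame
    annotations: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=ANNOTATION_COLUMNS))

    def __post_init__(self):
        self.counts = self.counts.copy()
        self.validate()

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.columns)

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise ValidationError("duplicate genome ids")
        if c.columns.duplicated().any():
            raise ValidationError("duplicate family ids")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("non-integer copy numbers")
            self.counts = c.astype(int)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = c.columns[(vals < 0).any(axis=0)][0]
            raise ValidationError(f"negative copy number in family {bad!r}")
        unknown = set(self.annotations.index) - set(c.columns)
        if unknown:
            raise ValidationError(
                f"annotated families absent from matrix: {sorted(unknown)[:5]}")

    def full_annotations(self) -> pd.DataFrame:
        """Annotation table covering every family, with defaults filled in."""
        ann = self.annotations.reindex(self.family_ids)
        ann["category"] = ann["category"].fillna("other")
        ann["subfamily"] = ann["subfamily"].fillna("")
        for flag in ("secreted", "pcwde", "fcwde"):
            ann[flag] = ann[flag].fillna(False).astype(bool)
        return ann

    def category_counts(self, category: str, secreted_only: bool = False) -> pd.Series:
        """Per-genome summed copy number over families of one category."""
        ann = self.full_annotations()
        mask = ann["category"] == category
        if secreted_only:
            mask &= ann["secreted"]
        fams = ann.index[mask]
        return self.counts[fams].sum(axis=1)


# ---------------------------------------------------------------------------
# Lifestyles
# ---------------------------------------------------------------------------

@dataclass
class LifestyleMap:
    """Genome -> lifestyle labels, with optional binary regrouping."""

    labels: pd.Series                       # genome_id -> lifestyle
    binary: pd.Series | None = None         # genome_id -> bool (target group)

    def __post_init__(self):
        bad = set(self.labels.unique()) - set(LIFESTYLES)
        if bad:
            raise ValidationError(f"unknown lifestyles: {sorted(bad)}")

    def binary_grouping(self, target: set[str] | frozenset[str]) -> pd.Series:
        """True for genomes whose lifestyle falls in ``target``."""
        return self.labels.isin(target)


# ---------------------------------------------------------------------------
# Amplicon survey
# ---------------------------------------------------------------------------

@dataclass
class AbundanceSurvey:
    """Samples x taxa read counts plus per-sample compartment/site metadata."""

    counts: pd.DataFrame                    # samples x taxa, ints
    metadata: pd.DataFrame                  # index sample_id; compartment, site

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("negative read counts in survey")
        if not set(self.counts.index) <= set(self.metadata.index):
            missing = set(self.counts.index) - set(self.metadata.index)
            raise ValidationError(f"samples without metadata: {sorted(missing)[:5]}")
        bad = set(self.metadata["compartment"].unique()) - set(COMPARTMENTS)
        if bad:
            raise ValidationError(f"unknown compartments: {sorted(bad)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def depths(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids) -> "AbundanceSurvey":
        return AbundanceSurvey(self.counts.loc[sample_ids],
                               self.metadata.loc[sample_ids])

    def compartment_samples(self, compartment: str) -> list[str]:
        if compartment not in set(self.metadata["compartment"]):
            raise ValidationError(f"compartment {compartment!r} absent from survey")
        return list(self.metadata.index[self.metadata["compartment"] == compartment]
                    .intersection(self.counts.index))


# ---------------------------------------------------------------------------
# Phenotype records
# ---------------------------------------------------------------------------

@dataclass
class PlatePhenotypeSet:
    """Per-plate germination and shoot-fresh-weight records.

    One row per plate: strain ("mock" for germ-free controls), Pi level
    (low/high), seeds sown, plants grown, and the SFW of each grown plant
    in mg (a list, serialized comma-joined in TSV).
    """

    plates: pd.DataFrame   # plate_id index; strain, pi_level, seeds_sown,
                           # plants_grown, sfw_mg (list of floats)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for pid, row in self.plates.iterrows():
            if row["plants_grown"] > row["seeds_sown"]:
                raise ValidationError(f"plate {pid}: plants grown > seeds sown")
            if len(row["sfw_mg"]) != row["plants_grown"]:
                raise ValidationError(
                    f"plate {pid}: {len(row['sfw_mg'])} SFW values for "
                    f"{row['plants_grown']} grown plants")
            if any(w <= 0 for w in row["sfw_mg"]):
                raise ValidationError(f"plate {pid}: non-positive SFW")
        if not set(self.plates["pi_level"].unique()) <= {"low", "high"}:
            raise ValidationError("pi_level must be 'low' or 'high'")


@dataclass
class QpcrRecords:
    """Per-sample qPCR quantification cycles for ITS1 and the UBQ10 control."""

    records: pd.DataFrame  # sample_id index; strain, cq_its1, cq_ubq10

    def __post_init__(self):
        if (self.records[["cq_its1", "cq_ubq10"]].to_numpy() <= 0).any():
            raise ValidationError("non-positive Cq value")


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

@dataclass
class DETable:
    """Per-gene differential-expression results for one strain."""

    strain: str
    genes: pd.DataFrame        # gene_id index; log2fc, padj
    gene_map: pd.Series        # gene_id -> orthogroup

    def __post_init__(self):
        padj = self.genes["padj"].to_numpy()
        if ((padj < 0) | (padj > 1)).any():
            raise ValidationError(f"strain {self.strain}: padj outside [0,1]")


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "tree": "tree.nwk",
    "matrix": "gene_counts.tsv",
    "annotations": "family_annotations.tsv",
    "lifestyles": "lifestyles.tsv",
    "survey_counts": "survey_counts.tsv",
    "survey_metadata": "survey_metadata.tsv",
    "plates": "plates.tsv",
    "qpcr": "qpcr.tsv",
    "de_dir": "de_tables",
    "gene_map": "gene_orthogroup_map.tsv",
}


@dataclass
class Bundle:
    """A coherent dataset: everything the pipeline consumes, cross-validated."""

    tree: Phylogeny
    matrix: GeneFamilyMatrix
    lifestyles: LifestyleMap
    survey: AbundanceSurvey | None = None
    plates: PlatePhenotypeSet | None = None
    qpcr: QpcrRecords | None = None
    de_tables: list[DETable] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        tips = set(self.tree.tip_names)
        genomes = set(self.matrix.genome_ids)
        only_matrix = genomes - tips
        if only_matrix:
            raise ValidationError(
                f"genomes absent from tree: {sorted(only_matrix)[:5]}")
        unlabeled = set(self.lifestyles.labels.index) - genomes
        if unlabeled:
            raise ValidationError(
                f"lifestyle labels for unknown genomes: {sorted(unlabeled)[:5]}")
        fams = set(self.matrix.family_ids)
        for det in self.de_tables:
            mapped = set(det.gene_map.unique())
            if not mapped <= fams:
                bad = sorted(mapped - fams)[:5]
                raise ValidationError(
                    f"strain {det.strain}: orthogroups not in matrix: {bad}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, **kw)


def _write_tsv(df: pd.DataFrame, path, float_format="%.12g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def read_gene_matrix(counts_path, annotations_path=None) -> GeneFamilyMatrix:
    counts = _read_tsv(counts_path)
    if annotations_path is not None and Path(annotations_path).exists():
        ann = _read_tsv(annotations_path, dtype={"subfamily": str})
        if len(ann):
            for flag in ("secreted", "pcwde", "fcwde"):
                ann[flag] = ann[flag].astype(bool)
            ann["subfamily"] = ann["subfamily"].fillna("")
        else:
            ann = pd.DataFrame(columns=ANNOTATION_COLUMNS)
    else:
        ann = pd.DataFrame(columns=ANNOTATION_COLUMNS)
    return GeneFamilyMatrix(counts, ann)


def write_gene_matrix(gfm: GeneFamilyMatrix, counts_path, annotations_path) -> None:
    _write_tsv(gfm.counts, counts_path)
    ann = gfm.annotations.copy()
    ann.index.name = "family_id"
    _write_tsv(ann, annotations_path)


def read_lifestyles(path) -> LifestyleMap:
    df = _read_tsv(path)
    binary = None
    if "target_group" in df.columns:
        binary = df["target_group"].astype(bool)
    return LifestyleMap(df["lifestyle"], binary)


def write_lifestyles(lsm: LifestyleMap, path) -> None:
    df = pd.DataFrame({"lifestyle": lsm.labels})
    if lsm.binary is not None:
        df["target_group"] = lsm.binary
    df.index.name = "genome_id"
    _write_tsv(df, path)


def read_survey(counts_path, metadata_path) -> AbundanceSurvey:
    return AbundanceSurvey(_read_tsv(counts_path), _read_tsv(metadata_path))


def write_survey(survey: AbundanceSurvey, counts_path, metadata_path) -> None:
    c = survey.counts.copy()
    c.index.name = "sample_id"
    _write_tsv(c, counts_path)
    m = survey.metadata.copy()
    m.index.name = "sample_id"
    _write_tsv(m, metadata_path)


def read_plates(path) -> PlatePhenotypeSet:
    df = _read_tsv(path, dtype={"sfw_mg": str})
    df["sfw_mg"] = [
        [float(x) for x in s.split(",")] if isinstance(s, str) and s else []
        for s in df["sfw_mg"]
    ]
    return PlatePhenotypeSet(df)


def write_plates(pps: PlatePhenotypeSet, path) -> None:
    df = pps.plates.copy()
    df["sfw_mg"] = [",".join(f"{x:.12g}" for x in v) for v in df["sfw_mg"]]
    df.index.name = "plate_id"
    _write_tsv(df, path)


def read_qpcr(path) -> QpcrRecords:
    return QpcrRecords(_read_tsv(path))


def write_qpcr(q: QpcrRecords, path) -> None:
    df = q.records.copy()
    df.index.name = "sample_id"
    _write_tsv(df, path)


def read_de_tables(de_dir, gene_map_path) -> list[DETable]:
    gm = _read_tsv(gene_map_path)
    out = []
    for f in sorted(Path(de_dir).glob("*.tsv")):
        strain = f.stem
        genes = _read_tsv(f)
        sub = gm[gm["strain"] == strain]["orthogroup"]
        out.append(DETable(strain, genes, sub))
    return out


def write_de_tables(tables: list[DETable], de_dir, gene_map_path) -> None:
    de_dir = Path(de_dir)
    de_dir.mkdir(parents=True, exist_ok=True)
    maps = []
    for det in tables:
        g = det.genes.copy()
        g.index.name = "gene_id"
        _write_tsv(g, de_dir / f"{det.strain}.tsv")
        m = pd.DataFrame({"orthogroup": det.gene_map})
        m["strain"] = det.strain
        maps.append(m)
    gm = pd.concat(maps)
    gm.index.name = "gene_id"
    _write_tsv(gm, gene_map_path)


def load_bundle(directory) -> Bundle:
    """Load and cross-validate a full dataset from ``directory``.

    Missing optional components (survey, phenotypes, expression) are left
    as ``None``; the three core files (tree, matrix, lifestyles) are
    required.
    """
    d = Path(directory)
    for key in ("tree", "matrix", "lifestyles"):
        if not (d / BUNDLE_FILES[key]).exists():
            raise FileNotFoundError(d / BUNDLE_FILES[key])
    tree = Phylogeny.read(d / BUNDLE_FILES["tree"])
    matrix = read_gene_matrix(d / BUNDLE_FILES["matrix"],
                              d / BUNDLE_FILES["annotations"])
    lifestyles = read_lifestyles(d / BUNDLE_FILES["lifestyles"])
    survey = plates = qpcr = None
    de_tables: list[DETable] = []
    if (d / BUNDLE_FILES["survey_counts"]).exists():
        survey = read_survey(d / BUNDLE_FILES["survey_counts"],
                             d / BUNDLE_FILES["survey_metadata"])
    if (d / BUNDLE_FILES["plates"]).exists():
        plates = read_plates(d / BUNDLE_FILES["plates"])
    if (d / BUNDLE_FILES["qpcr"]).exists():
        qpcr = read_qpcr(d / BUNDLE_FILES["qpcr"])
    if (d / BUNDLE_FILES["de_dir"]).exists():
        de_tables = read_de_tables(d / BUNDLE_FILES["de_dir"],
                                   d / BUNDLE_FILES["gene_map"])
    return Bundle(tree, matrix, lifestyles, survey, plates, qpcr, de_tables)


def write_bundle(bundle: Bundle, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.tree.write(d / BUNDLE_FILES["tree"])
    write_gene_matrix(bundle.matrix, d / BUNDLE_FILES["matrix"],
                      d / BUNDLE_FILES["annotations"])
    write_lifestyles(bundle.lifestyles, d / BUNDLE_FILES["lifestyles"])
    if bundle.survey is not None:
        write_survey(bundle.survey, d / BUNDLE_FILES["survey_counts"],
                     d / BUNDLE_FILES["survey_metadata"])
    if bundle.plates is not None:
        write_plates(bundle.plates, d / BUNDLE_FILES["plates"])
    if bundle.qpcr is not None:
        write_qpcr(bundle.qpcr, d / BUNDLE_FILES["qpcr"])
    if bundle.de_tables:
        write_de_tables(bundle.de_tables, d / BUNDLE_FILES["de_dir"],
                        d / BUNDLE_FILES["gene_map"])
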