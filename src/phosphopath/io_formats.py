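"""Readers and writers for the external formats the pipeline touches.

Quantitation tables are tab-delimited UTF-8 with a header row; missing
abundances are empty cells, never 0 (a zero would corrupt CVs and ratios).
Run identifiers encode the cell line and replicate as ``<line>.<replicate>``,
e.g. ``3KT.1``. Pathway memberships use GMT lines, protein→term annotations a
two-column TSV, and the ontology either a minimal OBO subset (id / name /
namespace / is_a; everything else ignored) or a two-column child→parent edge
list.
"""

from __future__ import annotations

import importlib.resources
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "QuantTable",
    "PeptideRecord",
    "Pathway",
    "PathwayCollection",
    "AnnotationSet",
    "OntologyGraph",
    "read_quant_table",
    "write_quant_table",
    "read_gmt",
    "write_gmt",
    "read_annotations",
    "write_annotations",
    "read_ontology",
    "write_edge_list",
    "read_fasta",
    "write_fasta",
    "load_ras_concurrence_table",
    "run_cell_line",
]

#: columns of the quant-table TSV that precede the per-run abundance columns
META_COLUMNS = ("peptide_sequence", "protein_accession", "gene_symbol", "sites", "is_standard")

RUN_SEPARATOR = "."


def run_cell_line(run_id: str) -> str:
    """Cell line encoded in a run identifier (``"A549.2"`` → ``"A549"``)."""
    line, sep, _ = run_id.rpartition(RUN_SEPARATOR)
    if not sep:
        raise ValueError(f"run id {run_id!r} has no '{RUN_SEPARATOR}<replicate>' suffix")
    return line


@dataclass
class PeptideRecord:
    """One phosphopeptide row: marked sequence, protein, sites, abundances.

    ``peptide_sequence`` carries phospho positions as a ``p`` prefix on the
    modified residue (``LSPpSPTSQR``). ``sites`` are residue+position labels
    on the protein (1-based), e.g. ``S392``.
    """

    peptide_id: str
    peptide_sequence: str
    protein_accession: str
    gene_symbol: str
    sites: tuple[str, ...]
    abundance: dict[str, float]
    is_standard: bool = False


@dataclass
class QuantTable:
    """Phosphopeptide × run abundance matrix with peptide metadata.

    ``meta`` is indexed by peptide id with columns ``peptide_sequence``,
    ``protein_accession``, ``gene_symbol``, ``sites`` (semicolon-joined) and
    ``is_standard``; ``abundance`` shares the index, one float column per run
    (NaN = not detected).
    """

    meta: pd.DataFrame
    abundance: pd.DataFrame
    standard_row_id: str | None = None

    def __post_init__(self) -> None:
        self.meta.index.name = "peptide_id"
        self.abundance.index.name = "peptide_id"
        runs = list(self.abundance.columns)
        if len(set(runs)) != len(runs):
            raise ValueError("duplicate run identifiers in quant table")
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("negative abundance in quant table")
        std = self.meta.index[self.meta["is_standard"].astype(bool)]
        if self.standard_row_id is None and len(std) == 1:
            self.standard_row_id = std[0]
        if len(std) > 1:
            raise ValueError("more than one internal-standard row")

    @property
    def runs(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def run_classes(self) -> dict[str, str]:
        """Mapping run id → cell line."""
        return {r: run_cell_line(r) for r in self.runs}

    @property
    def cell_lines(self) -> list[str]:
        seen: list[str] = []
        for r in self.runs:
            line = run_cell_line(r)
            if line not in seen:
                seen.append(line)
        return seen

    def require_standard(self) -> str:
        if self.standard_row_id is None:
            raise ValueError("quant table has no internal-standard row")
        return self.standard_row_id

    def records(self) -> list[PeptideRecord]:
        out = []
        for pid, row in self.meta.iterrows():
            ab = self.abundance.loc[pid]
            out.append(
                PeptideRecord(
                    peptide_id=str(pid),
                    peptide_sequence=row["peptide_sequence"],
                    protein_accession=row["protein_accession"],
                    gene_symbol=row["gene_symbol"],
                    sites=tuple(s for s in str(row["sites"]).split(";") if s),
                    abundance={r: v for r, v in ab.items() if pd.notna(v)},
                    is_standard=bool(row["is_standard"]),
                )
            )
        return out


def read_quant_table(path, *, require_standard: bool = False) -> QuantTable:
    """Read a tab-delimited quant table; empty cells stay missing (NaN)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ValueError(f"duplicate run identifiers in quant table: {sorted(dupes)}")
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str}, keep_default_na=False, na_values=[""])
    missing = [c for c in ("peptide_id",) + META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"quant table missing columns: {missing}")
    df = df.set_index("peptide_id")
    run_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not run_cols:
        raise ValueError("quant table has no run columns")
    for c in run_cols:
        run_cell_line(c)  # validates the <line>.<rep> shape
    meta = df[list(META_COLUMNS)].copy()
    meta["is_standard"] = meta["is_standard"].fillna(0).astype(int).astype(bool)
    meta["sites"] = meta["sites"].fillna("")
    abundance = df[run_cols].astype(float)
    table = QuantTable(meta=meta, abundance=abundance)
    if require_standard:
        table.require_standard()
    return table


def write_quant_table(table: QuantTable, path) -> None:
    out = table.meta.copy()
    out["is_standard"] = out["is_standard"].astype(int)
    out = pd.concat([out, table.abundance], axis=1)
    out.index.name = "peptide_id"
    out.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# pathway memberships (GMT)


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    members: frozenset[str]


@dataclass
class PathwayCollection:
    """Named protein sets, e.g. NCI-PID signaling pathways."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def add(self, pathway_id: str, name: str, members: Iterable[str]) -> None:
        if pathway_id in self.pathways:
            raise ValueError(f"duplicate pathway id {pathway_id!r}")
        members = frozenset(members)
        if not members:
            raise ValueError(f"pathway {pathway_id!r} has no members")
        self.pathways[pathway_id] = Pathway(pathway_id, name, members)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.values())

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self.pathways[pathway_id]

    def ids(self) -> list[str]:
        return list(self.pathways)


def read_gmt(path) -> PathwayCollection:
    coll = PathwayCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            coll.add(fields[0], fields[1], fields[2:])
    return coll


def write_gmt(coll: PathwayCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pw in coll:
            fh.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.members)]) + "\n")


# ---------------------------------------------------------------------------
# annotations + ontology

AnnotationSet = dict[str, set[str]]  # protein → ontology term ids


def read_annotations(path) -> AnnotationSet:
    """Two-column TSV: protein <tab> term, one association per line."""
    ann: AnnotationSet = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"annotation line {lineno}: expected 2 fields")
            ann.setdefault(parts[0], set()).add(parts[1])
    return ann


def write_annotations(ann: AnnotationSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for protein in sorted(ann):
            for term in sorted(ann[protein]):
                fh.write(f"{protein}\t{term}\n")


@dataclass
class OntologyGraph:
    """Ontology DAG of is_a relations: edges point child → parent.

    One root per namespace; roots are excluded from propagated annotation
    sets so that trivially shared top terms never inflate similarity.
    """

    graph: nx.DiGraph
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology is_a graph contains a cycle")
        for term in self.graph.nodes:
            self.namespaces.setdefault(term, "default")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of *term*, excluding the term itself."""
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in ontology")
        return nx.descendants(self.graph, term)

    def namespace(self, term: str) -> str:
        return self.namespaces.get(term, "default")


def read_ontology(path, format: str = "obo-lite") -> OntologyGraph:
    """Build an :class:`OntologyGraph` from an OBO file or a child→parent TSV.

    Only ``is_a`` relations are consumed; any other OBO relationship
    (part_of, regulates, ...) is ignored by construction.
    """
    if format == "obo-lite":
        multi = obonet.read_obo(path)  # edges child → parent, key = relation
        g = nx.DiGraph()
        namespaces: dict[str, str] = {}
        for term, data in multi.nodes(data=True):
            g.add_node(term)
            namespaces[term] = data.get("namespace", "default")
        for child, parent, rel in multi.edges(keys=True):
            if rel == "is_a":
                g.add_edge(child, parent)
        return OntologyGraph(graph=g, namespaces=namespaces)
    if format == "edge-list":
        g = nx.DiGraph()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"edge list line {lineno}: expected 2 fields")
                g.add_edge(parts[0], parts[1])
        return OntologyGraph(graph=g)
    raise ValueError(f"unknown ontology format {format!r}")


def write_edge_list(graph: OntologyGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for child, parent in sorted(graph.graph.edges):
            fh.write(f"{child}\t{parent}\n")


def validate_annotations(ann: AnnotationSet, graph: OntologyGraph) -> None:
    """Raise if any annotated term is absent from the ontology."""
    orphans = {t for terms in ann.values() for t in terms} - graph.terms
    if orphans:
        raise ValueError(f"annotated terms missing from ontology: {sorted(orphans)[:5]}")


# ---------------------------------------------------------------------------
# protein sequences


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# packaged fixture


def load_ras_concurrence_table():
    """Published log2-ratio table of Ras-regulated phosphorylation events.

    19 phosphopeptide rows across four comparisons against the immortalized
    bronchial line 3KT (3KTR/3KT, A549/3KT, H322/3KT, H1299/3KT), with −9999
    marking peptides detected in 3KT but not in the test line. Returns a
    :class:`phosphopath.quant.RatioTable`.
    """
    from .quant import SENTINEL_REF_ONLY, SENTINEL_TEST_ONLY, RatioTable  # deferred: avoids cycle

    text = importlib.resources.files("phosphopath.data").joinpath("ras_concurrence_ratios.tsv").read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t")
    df.index = [f"{row.gene_symbol}_{row.site}" for row in df.itertuples()]
    meta = df[["gene_symbol", "protein_name", "accession", "peptide_sequence", "site"]].copy()
    meta = meta.rename(columns={"accession": "protein_accession", "site": "sites"})
    ratios = df[["3KTR/3KT", "A549/3KT", "H322/3KT", "H1299/3KT"]].astype(float)
    assert set(ratios.values[ratios.values.round() == -9999]) <= {SENTINEL_REF_ONLY}
    assert SENTINEL_TEST_ONLY not in ratios.values
    return RatioTable(meta=meta, ratios=ratios)
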