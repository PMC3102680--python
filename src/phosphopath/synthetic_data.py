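"""Synthetic phosphoproteomics datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes: five
cell lines × three LC-MS/MS runs, a spiked β-casein internal-standard
phosphopeptide in every run, log2-normal peptide abundances with per-run
multiplicative scale factors and replicate noise, planted log2 effects (per
peptide and per active pathway), class-exclusive detections (peptides fully
absent in one line, which become ±9999 sentinels downstream), phosphosite
sequence contexts drawn from a configurable motif mix, pathway memberships
arranged in two annotation communities, and a small rooted GO-like is_a
tree. Everything is a deterministic function of the seed.

Proteins are laid out as concatenated 13-mer site windows, so the ±6
context of every phosphosite is fully determined by its generated window
and re-extractable from the FASTA.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationSet,
    OntologyGraph,
    PathwayCollection,
    QuantTable,
    write_annotations,
    write_edge_list,
    write_fasta,
    write_gmt,
    write_quant_table,
)
from .motifs import AMINO_ACIDS, FLANK, MotifClass

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_dataset",
    "simulate_null_dataset",
    "write_dataset",
]

STANDARD_PEPTIDE_ID = "STD_bcasein"
STANDARD_SEQUENCE = "FQpSEEQQQTEDELQDK"  # the spiked β-casein phosphopeptide


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters; the defaults mirror the emulated experiment.

    Abundances follow a log2-normal model: the observed value for peptide
    *j* in run *(line, r)* is ``2**(baseline_j + effect_j,line + noise) ×
    run_scale``. ``replicate_noise_sd`` is in log2 units; the default 0.25
    corresponds to replicate CVs in the vicinity of the 20% QC bound.
    ``motif_mix`` defaults to a site population dominated by
    proline-directed contexts, as observed for Ras-regulated sites.
    """

    cell_lines: tuple[str, ...] = ("3KT", "3KTR", "A549", "H322", "H1299")
    reference_line: str = "3KT"
    replicates_per_line: int = 3
    n_proteins: int = 200
    peptides_per_protein_lambda: float = 1.2  # peptides = 1 + Poisson(λ)
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    run_scale_factors: tuple[float, ...] | None = None  # per run; default 2**U(−1,1)
    replicate_noise_sd: float = 0.25
    planted_effects: tuple[tuple[str, str, float], ...] | None = None  # (peptide, line, shift)
    n_regulated: int = 0
    effect_size_log2: float = 2.0
    negative_effect_fraction: float = 0.5
    effect_lines: tuple[str, ...] = ("3KTR",)
    class_exclusive_fraction: float = 0.0
    motif_mix: dict[MotifClass, float] = field(
        default_factory=lambda: {
            MotifClass.PROLINE_DIRECTED: 0.60,
            MotifClass.BASOPHILIC: 0.20,
            MotifClass.ACIDOPHILIC: 0.10,
            MotifClass.OTHER: 0.10,
        }
    )
    n_pathways: int = 20
    members_per_pathway: int = 10
    n_active_pathways: int = 0
    pathway_effect_log2: float = 1.0
    terms_per_protein: int = 3
    annotation_noise: float = 0.10
    ontology_depth: int = 4
    ontology_branching: int = 3
    standard_abundance: float = 2.0**18
    seed: int = 0

    def validate(self) -> None:
        if self.reference_line not in self.cell_lines:
            raise ValueError("reference_line must be one of cell_lines")
        if not set(self.effect_lines) <= set(self.cell_lines):
            raise ValueError("effect_lines must be a subset of cell_lines")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")
        if abs(sum(self.motif_mix.values()) - 1.0) > 1e-9:
            raise ValueError("motif_mix probabilities must sum to 1")
        if self.n_active_pathways > self.n_pathways:
            raise ValueError("more active pathways than pathways")
        if self.members_per_pathway * 2 > self.n_proteins:
            raise ValueError("too few proteins for two pathway communities")
        if not 0 <= self.class_exclusive_fraction < 1:
            raise ValueError("class_exclusive_fraction must lie in [0, 1)")

    @property
    def runs(self) -> list[str]:
        return [f"{line}.{r}" for line in self.cell_lines for r in range(1, self.replicates_per_line + 1)]


@dataclass
class GroundTruth:
    """What the generator planted, keyed the way downstream stages report."""

    effects: dict[tuple[str, str], float]          # (peptide_id, line) → log2 shift
    active_pathways: list[str]
    site_class: dict[str, MotifClass]              # peptide_id → consensus class
    exclusive_absent: dict[str, str]               # peptide_id → line it is absent from
    run_scale_factors: dict[str, float]

    def regulated_peptides(self, line: str, min_abs_effect: float = 0.0) -> dict[str, int]:
        """Peptide → direction (+1/−1) for peptides with a planted effect in *line*."""
        out = {}
        for (pid, ln), eff in self.effects.items():
            if ln == line and abs(eff) > min_abs_effect:
                out[pid] = 1 if eff > 0 else -1
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "effects": [[pid, line, eff] for (pid, line), eff in sorted(self.effects.items())],
                "active_pathways": self.active_pathways,
                "site_class": {k: v.value for k, v in sorted(self.site_class.items())},
                "exclusive_absent": dict(sorted(self.exclusive_absent.items())),
                "run_scale_factors": dict(sorted(self.run_scale_factors.items())),
            },
            indent=1,
        )


@dataclass
class SyntheticDataset:
    quant: QuantTable
    sequences: dict[str, str]
    pathways: PathwayCollection
    annotations: AnnotationSet
    ontology: OntologyGraph
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------


def _draw_window(rng: np.random.Generator, cls: MotifClass) -> str:
    """Random 13-mer whose constrained offsets realise exactly one class."""
    cells = list(rng.choice(list(AMINO_ACIDS), size=2 * FLANK + 1))
    cells[FLANK] = "S" if rng.random() < 0.75 else "T"
    p1, m3, p3 = FLANK + 1, FLANK - 3, FLANK + 3
    not_in = lambda pos, bad: _redraw(rng, bad) if cells[pos] in bad else cells[pos]  # noqa: E731
    if cls is MotifClass.PROLINE_DIRECTED:
        cells[p1] = "P"
    elif cls is MotifClass.BASOPHILIC:
        cells[m3] = "R"
        cells[p1] = not_in(p1, set("PDE"))
        cells[p3] = not_in(p3, set("E"))
    elif cls is MotifClass.ACIDOPHILIC:
        cells[p1] = "D" if rng.random() < 0.5 else "E"
        cells[m3] = not_in(m3, set("R"))
    else:
        cells[p1] = not_in(p1, set("PDE"))
        cells[m3] = not_in(m3, set("R"))
        cells[p3] = not_in(p3, set("E"))
    return "".join(cells)


def _redraw(rng: np.random.Generator, forbidden: set[str]) -> str:
    allowed = [a for a in AMINO_ACIDS if a not in forbidden]
    return str(rng.choice(allowed))


def _build_ontology(depth: int, branching: int) -> tuple[OntologyGraph, list[list[str]]]:
    """Rooted is_a tree; returns the graph and the leaf pools of the first
    two depth-1 subtrees (the annotation communities)."""
    g = nx.DiGraph()
    counter = 0

    def new_term() -> str:
        nonlocal counter
        term = f"GO:{counter:07d}"
        counter += 1
        return term

    root = new_term()
    g.add_node(root)
    frontier = [(root, 0)]
    children_of: dict[str, list[str]] = {}
    while frontier:
        parent, d = frontier.pop(0)
        if d == depth:
            continue
        kids = [new_term() for _ in range(branching)]
        children_of[parent] = kids
        for kid in kids:
            g.add_edge(kid, parent)
            frontier.append((kid, d + 1))
    graph = OntologyGraph(graph=g, namespaces={t: "biological_process" for t in g.nodes})
    leaves = [t for t in g.nodes if g.in_degree(t) == 0]
    pools = []
    for comm_root in children_of.get(root, [])[:2]:
        sub = nx.ancestors(g, comm_root) | {comm_root}  # edges child→parent: ancestors = below
        pools.append(sorted(set(leaves) & sub))
    return graph, pools


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full input tuple plus ground truth from one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- proteins, peptides, sites -------------------------------------
    classes = list(config.motif_mix)
    probs = [config.motif_mix[c] for c in classes]
    sequences: dict[str, str] = {}
    meta_rows: list[dict] = []
    site_class: dict[str, MotifClass] = {}
    protein_of_peptide: dict[str, str] = {}
    for p in range(config.n_proteins):
        acc = f"PROT{p + 1:04d}"
        gene = f"G{p + 1:04d}"
        n_pep = 1 + int(rng.poisson(config.peptides_per_protein_lambda))
        windows = []
        for j in range(n_pep):
            cls = classes[int(rng.choice(len(classes), p=probs))]
            window = _draw_window(rng, cls)
            pid = f"{acc}.p{j + 1}"
            pos = 13 * j + FLANK + 1
            site = f"{window[FLANK]}{pos}"
            marked = window[:FLANK] + "p" + window[FLANK:]
            windows.append(window)
            site_class[pid] = cls
            protein_of_peptide[pid] = acc
            meta_rows.append(
                {
                    "peptide_id": pid,
                    "peptide_sequence": marked,
                    "protein_accession": acc,
                    "gene_symbol": gene,
                    "sites": site,
                    "is_standard": False,
                }
            )
        sequences[acc] = "".join(windows)
    peptide_ids = [r["peptide_id"] for r in meta_rows]

    # --- pathways in two communities ------------------------------------
    accs = sorted(sequences)
    half = len(accs) // 2
    pools = [accs[:half], accs[half:]]
    pathways = PathwayCollection()
    pathway_ids = [f"PW{i + 1:03d}" for i in range(config.n_pathways)]
    for i, pw_id in enumerate(pathway_ids):
        pool = pools[i % 2]
        members = rng.choice(pool, size=min(config.members_per_pathway, len(pool)), replace=False)
        pathways.add(pw_id, f"synthetic pathway {i + 1} (community {i % 2})", list(members))
    active = sorted(rng.choice(pathway_ids, size=config.n_active_pathways, replace=False).tolist())

    # --- planted effects -------------------------------------------------
    effects: dict[tuple[str, str], float] = {}
    for pw_id in active:
        for acc in pathways[pw_id].members:
            for pid, owner in protein_of_peptide.items():
                if owner == acc:
                    for line in config.effect_lines:
                        effects[(pid, line)] = effects.get((pid, line), 0.0) + config.pathway_effect_log2
    if config.planted_effects is not None:
        for pid, line, shift in config.planted_effects:
            if pid not in protein_of_peptide:
                raise ValueError(f"planted effect names unknown peptide {pid!r}")
            effects[(pid, line)] = effects.get((pid, line), 0.0) + shift
    elif config.n_regulated:
        untouched = [p for p in peptide_ids if all((p, ln) not in effects for ln in config.cell_lines)]
        chosen = rng.choice(untouched, size=config.n_regulated, replace=False)
        signs = np.where(rng.random(config.n_regulated) < config.negative_effect_fraction, -1.0, 1.0)
        for pid, sign in zip(chosen, signs):
            for line in config.effect_lines:
                effects[(pid, line)] = sign * config.effect_size_log2

    # --- class-exclusive detections --------------------------------------
    exclusive_absent: dict[str, str] = {}
    n_exclusive = int(round(config.class_exclusive_fraction * len(peptide_ids)))
    if n_exclusive:
        candidates = [p for p in peptide_ids if all((p, ln) not in effects for ln in config.cell_lines)]
        chosen = rng.choice(candidates, size=n_exclusive, replace=False)
        non_ref = [ln for ln in config.cell_lines if ln != config.reference_line]
        for i, pid in enumerate(chosen):
            # alternate: absent in reference (→ test-only) vs absent in a test line
            exclusive_absent[pid] = config.reference_line if i % 2 == 0 else non_ref[i % len(non_ref)]

    # --- abundances -------------------------------------------------------
    runs = config.runs
    # drawn unconditionally so explicit factors do not shift the rng stream
    scales = 2.0 ** rng.uniform(-1.0, 1.0, size=len(runs))
    if config.run_scale_factors is not None:
        if len(config.run_scale_factors) != len(runs):
            raise ValueError("run_scale_factors must supply one factor per run")
        scales = np.asarray(config.run_scale_factors, dtype=float)
    scale_of = dict(zip(runs, scales))

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=len(peptide_ids))
    noise = rng.normal(0.0, config.replicate_noise_sd, size=(len(peptide_ids), len(runs))) \
        if config.replicate_noise_sd > 0 else np.zeros((len(peptide_ids), len(runs)))
    log2_mat = baseline[:, None] + noise
    for col, run in enumerate(runs):
        line = run.rsplit(".", 1)[0]
        for row, pid in enumerate(peptide_ids):
            eff = effects.get((pid, line))
            if eff:
                log2_mat[row, col] += eff
    abundance = 2.0**log2_mat * scales[None, :]
    for pid, absent_line in exclusive_absent.items():
        row = peptide_ids.index(pid)
        for col, run in enumerate(runs):
            if run.rsplit(".", 1)[0] == absent_line:
                abundance[row, col] = np.nan

    meta = pd.DataFrame(meta_rows).set_index("peptide_id")
    ab_df = pd.DataFrame(abundance, index=peptide_ids, columns=runs)
    std_meta = pd.DataFrame(
        [{
            "peptide_sequence": STANDARD_SEQUENCE,
            "protein_accession": "P02666",
            "gene_symbol": "CSN2",
            "sites": "S64",
            "is_standard": True,
        }],
        index=[STANDARD_PEPTIDE_ID],
    )
    std_ab = pd.DataFrame(
        [[scale_of[r] * config.standard_abundance for r in runs]],
        index=[STANDARD_PEPTIDE_ID],
        columns=runs,
    )
    quant = QuantTable(
        meta=pd.concat([std_meta, meta]),
        abundance=pd.concat([std_ab, ab_df]),
    )

    # --- annotations over a two-community ontology -----------------------
    ontology, leaf_pools = _build_ontology(config.ontology_depth, config.ontology_branching)
    all_leaves = sorted(set(leaf_pools[0]) | set(leaf_pools[1])) if len(leaf_pools) == 2 else []
    annotations: AnnotationSet = {}
    for i, acc in enumerate(accs):
        pool = leaf_pools[0] if acc in pools[0] else leaf_pools[1]
        terms = set()
        for _ in range(config.terms_per_protein):
            source = all_leaves if (all_leaves and rng.random() < config.annotation_noise) else pool
            terms.add(str(rng.choice(source)))
        annotations[acc] = terms

    truth = GroundTruth(
        effects=effects,
        active_pathways=active,
        site_class=site_class,
        exclusive_absent=exclusive_absent,
        run_scale_factors=scale_of,
    )
    return SyntheticDataset(
        quant=quant,
        sequences=sequences,
        pathways=pathways,
        annotations=annotations,
        ontology=ontology,
        truth=truth,
        config=config,
    )


def simulate_null_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Same generator with every planted effect removed: two isogenic-like
    classes differing only by replicate noise."""
    null_cfg = dataclasses.replace(
        config, planted_effects=None, n_regulated=0, n_active_pathways=0
    )
    return simulate_dataset(null_cfg)


def write_dataset(ds: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write every artifact in the pipeline's on-disk dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "quant": out / "quant.tsv",
        "fasta": out / "proteins.fasta",
        "gmt": out / "pathways.gmt",
        "annotations": out / "annotations.tsv",
        "ontology": out / "ontology_edges.tsv",
        "truth": out / "ground_truth.json",
    }
    write_quant_table(ds.quant, paths["quant"])
    write_fasta(ds.sequences, paths["fasta"])
    write_gmt(ds.pathways, paths["gmt"])
    write_annotations(ds.annotations, paths["annotations"])
    write_edge_list(ds.ontology, paths["ontology"])
    paths["truth"].write_text(ds.truth.to_json())
    return paths
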