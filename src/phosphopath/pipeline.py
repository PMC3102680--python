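"""End-to-end orchestration: simulate/load → quantify → motifs → pathway
activity → pathway clustering, with on-disk TSV artifacts between stages and
a run manifest (seed, config hash, row counts) for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats, motifs, pathway_activity, pathway_clustering, quant
from .synthetic_data import SimulationConfig, SyntheticDataset, simulate_dataset, write_dataset

__all__ = ["PipelineConfig", "ReportBundle", "validate_config", "run_full_pipeline"]

logger = logging.getLogger("phosphopath")

ALL_STAGES = ("quant", "motifs", "pathways", "cluster")


@dataclass
class PipelineConfig:
    """One config drives the whole run; exactly one of ``input_paths`` /
    ``simulation`` supplies the data."""

    comparisons: list[quant.ComparisonSpec]
    simulation: SimulationConfig | None = None
    input_paths: dict[str, str] | None = None  # keys: quant, fasta, gmt, annotations, ontology
    concurrence_require: list[str] = field(default_factory=list)
    concurrence_exclude: list[str] = field(default_factory=list)
    qc: quant.QCConfig = field(default_factory=quant.QCConfig)
    enrichment: motifs.EnrichmentConfig = field(default_factory=motifs.EnrichmentConfig)
    activity: pathway_activity.ActivityConfig = field(default_factory=pathway_activity.ActivityConfig)
    clustering_threshold: float = 0.5
    clustering_profile: str = "correlation"
    centering: str = "mean"
    stages: tuple[str, ...] = ALL_STAGES
    out_dir: str | None = None
    seed: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        comparisons = [
            quant.ComparisonSpec(
                test=c["test"],
                reference=c["reference"],
                regulation_threshold=c.get("regulation_threshold", 1.0),
            )
            for c in raw.get("comparisons", [])
        ]
        sim = raw.get("simulation")
        sim_cfg = None
        if sim is not None:
            known = {f.name for f in dataclasses.fields(SimulationConfig)}
            unknown = set(sim) - known
            if unknown:
                raise ValueError(f"unknown simulation fields: {sorted(unknown)}")
            if "cell_lines" in sim:
                sim["cell_lines"] = tuple(sim["cell_lines"])
            if "effect_lines" in sim:
                sim["effect_lines"] = tuple(sim["effect_lines"])
            sim_cfg = SimulationConfig(**sim)
        kwargs = {}
        for key in (
            "input_paths", "concurrence_require", "concurrence_exclude",
            "clustering_threshold", "clustering_profile", "centering",
            "out_dir", "seed", "log_level",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        if "qc" in raw:
            kwargs["qc"] = quant.QCConfig(**raw["qc"])
        if "enrichment" in raw:
            kwargs["enrichment"] = motifs.EnrichmentConfig(**raw["enrichment"])
        if "activity" in raw:
            kwargs["activity"] = pathway_activity.ActivityConfig(**raw["activity"])
        return cls(comparisons=comparisons, simulation=sim_cfg, **kwargs)


@dataclass
class ReportBundle:
    ratios: quant.RatioTable
    calls: pd.DataFrame
    counts: pd.DataFrame                       # per comparison: quantified/up/down
    concurrence: dict[str, list[str]] | None
    enrichments: dict[str, list[motifs.MotifEnrichment]]
    frequencies: dict[str, motifs.SubsetFrequencies]
    homogeneity: pd.DataFrame | None
    activity: dict[str, pd.DataFrame]
    similarity: pd.DataFrame | None
    clusters: pathway_clustering.ClusterResult | None
    manifest: dict


def validate_config(config: PipelineConfig) -> list[str]:
    """Empty list iff the config is runnable; otherwise human-readable findings."""
    findings: list[str] = []
    has_sim, has_paths = config.simulation is not None, bool(config.input_paths)
    if has_sim == has_paths:
        findings.append("exactly one of simulation / input_paths must be supplied")
    if not config.comparisons:
        findings.append("no comparisons configured")
    for spec in config.comparisons:
        if spec.regulation_threshold <= 0:
            findings.append(f"regulation_threshold must be > 0 in {spec.label}")
    labels = {s.label for s in config.comparisons}
    for comp in list(config.concurrence_require) + list(config.concurrence_exclude):
        if comp not in labels:
            findings.append(f"concurrence names unknown comparison {comp!r}")
    unknown_stages = set(config.stages) - set(ALL_STAGES)
    if unknown_stages:
        findings.append(f"unknown stages: {sorted(unknown_stages)}")
    if has_paths:
        if "quant" not in config.input_paths:
            findings.append("input_paths must include 'quant' (stage quant)")
        if "pathways" in config.stages and "gmt" not in config.input_paths:
            findings.append("pathway stage requires input_paths['gmt']")
        if "cluster" in config.stages and not {"gmt", "annotations", "ontology"} <= set(config.input_paths):
            findings.append("cluster stage requires gmt, annotations and ontology inputs")
    if not 0 < config.clustering_threshold <= 1:
        findings.append("clustering_threshold must lie in (0, 1]")
    return findings


def _load_inputs(config: PipelineConfig):
    paths = config.input_paths
    table = io_formats.read_quant_table(paths["quant"], require_standard=True)
    sequences = io_formats.read_fasta(paths["fasta"]) if "fasta" in paths else {}
    pathways = io_formats.read_gmt(paths["gmt"]) if "gmt" in paths else None
    ann = io_formats.read_annotations(paths["annotations"]) if "annotations" in paths else None
    onto = None
    if "ontology" in paths:
        fmt = "obo-lite" if str(paths["ontology"]).endswith(".obo") else "edge-list"
        onto = io_formats.read_ontology(paths["ontology"], format=fmt)
    return table, sequences, pathways, ann, onto


def _site_windows(meta: pd.DataFrame, sequences: dict[str, str]) -> pd.Series:
    """One ±6 window per peptide: from the protein sequence when available
    (full context), else from the marked peptide itself (terminal padding)."""
    out = {}
    for pid, row in meta.iterrows():
        if row.get("is_standard", False):
            continue
        acc = row["protein_accession"]
        sites = [s for s in str(row["sites"]).split(";") if s]
        if acc in sequences and sites:
            pos = int(sites[0][1:])
            out[pid] = motifs.extract_window(sequences[acc], pos)
        else:
            out[pid] = motifs.window_from_marked_peptide(row["peptide_sequence"])
    return pd.Series(out, name="window")


def run_full_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every configured stage; artifacts land in ``config.out_dir``."""
    logging.basicConfig(level=config.log_level)
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid pipeline config: " + "; ".join(findings))
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage: data ------------------------------------------------------
    if config.simulation is not None:
        sim_cfg = config.simulation
        if config.seed is not None:
            sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
        dataset: SyntheticDataset | None = simulate_dataset(sim_cfg)
        if out_dir:
            write_dataset(dataset, out_dir / "inputs")
        table, sequences = dataset.quant, dataset.sequences
        pathways, ann, onto = dataset.pathways, dataset.annotations, dataset.ontology
    else:
        try:
            dataset = None
            table, sequences, pathways, ann, onto = _load_inputs(config)
        except Exception as exc:
            raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    # --- stage: quant -----------------------------------------------------
    try:
        normalized = quant.normalize_to_standard(table)
        summary = quant.summarize_replicates(normalized, config.qc)
        meta = table.meta.drop(index=[table.standard_row_id]) if table.standard_row_id else table.meta
        means = summary.mean.drop(index=[table.standard_row_id], errors="ignore")
        ratio_table = quant.log2_ratio_table(means, config.comparisons, meta=meta)
        ratio_table = quant.center_ratios(ratio_table, method=config.centering)
        calls = quant.call_regulation_table(ratio_table, specs=config.comparisons)
    except Exception as exc:
        raise RuntimeError(f"stage 'quant' failed: {exc}") from exc

    count_rows = []
    for spec in config.comparisons:
        col = calls[spec.label]
        n_quant = int(ratio_table.ordinary_mask()[spec.label].sum())
        n_up = int((col == quant.RegulationCall.UP).sum())
        n_down = int((col == quant.RegulationCall.DOWN).sum())
        count_rows.append({"comparison": spec.label, "quantified": n_quant, "up": n_up, "down": n_down})
        logger.info("quant %s: quantified=%d up=%d down=%d", spec.label, n_quant, n_up, n_down)
    counts = pd.DataFrame(count_rows).set_index("comparison")

    concurrence = None
    if config.concurrence_require:
        concurrence = quant.concurrent_regulation(
            ratio_table, config.concurrence_require, config.concurrence_exclude
        )
        logger.info(
            "concurrence: %d up, %d down proteins", len(concurrence["up"]), len(concurrence["down"])
        )

    # --- stage: motifs ----------------------------------------------------
    enrichments: dict[str, list[motifs.MotifEnrichment]] = {}
    frequencies: dict[str, motifs.SubsetFrequencies] = {}
    homogeneity = None
    if "motifs" in config.stages:
        try:
            windows = _site_windows(table.meta, sequences)
            regulated_mask = calls.isin([quant.RegulationCall.UP, quant.RegulationCall.DOWN])
            for spec in config.comparisons:
                quantified = ratio_table.ordinary_mask()[spec.label]
                bg = windows.reindex(quantified[quantified].index).dropna().tolist()
                fg = windows.reindex(regulated_mask.index[regulated_mask[spec.label]]).dropna().tolist()
                if fg and bg:
                    enrichments[spec.label] = motifs.motifx_enrich(fg, bg, config.enrichment)
                    frequencies[spec.label] = motifs.subset_frequencies(
                        [motifs.classify_window(w) for w in fg]
                    )
            pairs = []
            labels = [s.label for s in config.comparisons if s.label in frequencies]
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    stat, dof, p = motifs.homogeneity_test(
                        frequencies[a].as_vector(), frequencies[b].as_vector()
                    )
                    pairs.append({"comparison_a": a, "comparison_b": b, "chi2": stat, "dof": dof, "p": p})
            homogeneity = pd.DataFrame(pairs) if pairs else None
        except Exception as exc:
            raise RuntimeError(f"stage 'motifs' failed: {exc}") from exc

    # --- stage: pathway activity ------------------------------------------
    activity: dict[str, pd.DataFrame] = {}
    if "pathways" in config.stages and pathways is not None:
        try:
            levels = np.log2(normalized.abundance.drop(index=[table.standard_row_id], errors="ignore"))
            protein_of = meta["protein_accession"]
            protein_matrix = pathway_activity.protein_representative_values(
                levels, protein_of, aggregation=config.activity.aggregation
            )
            regulated_proteins = {
                spec.label: set(
                    meta.loc[
                        calls.index[calls[spec.label].isin([quant.RegulationCall.UP, quant.RegulationCall.DOWN])],
                        "protein_accession",
                    ]
                )
                for spec in config.comparisons
            }
            activity = pathway_activity.score_all_pathways(
                protein_matrix, pathways, config.comparisons, config.activity, regulated_proteins
            )
            for label, df in activity.items():
                logger.info("pathways %s: %d pathways scored", label, len(df))
        except Exception as exc:
            raise RuntimeError(f"stage 'pathways' failed: {exc}") from exc

    # --- stage: clustering ------------------------------------------------
    similarity = None
    clusters = None
    if "cluster" in config.stages and pathways is not None and ann is not None and onto is not None:
        try:
            similarity = pathway_clustering.similarity_matrix(pathways, ann, onto)
            clusters = pathway_clustering.cluster_pathways(
                similarity, threshold=config.clustering_threshold, profile=config.clustering_profile
            )
            logger.info("cluster: %d clusters at threshold %.2f", len(clusters.clusters), config.clustering_threshold)
        except Exception as exc:
            raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc

    manifest = _manifest(config)
    bundle = ReportBundle(
        ratios=ratio_table,
        calls=calls,
        counts=counts,
        concurrence=concurrence,
        enrichments=enrichments,
        frequencies=frequencies,
        homogeneity=homogeneity,
        activity=activity,
        similarity=similarity,
        clusters=clusters,
        manifest=manifest,
    )
    if out_dir:
        _write_bundle(bundle, out_dir)
    return bundle


def _manifest(config: PipelineConfig) -> dict:
    from . import __version__

    def sanitize(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            o = dataclasses.asdict(o)
        if isinstance(o, dict):
            return {str(k): sanitize(v) for k, v in o.items()}
        if isinstance(o, (set, frozenset)):
            return sorted(str(x) for x in o)
        if isinstance(o, (list, tuple)):
            return [sanitize(x) for x in o]
        if isinstance(o, (str, int, float, bool)) or o is None:
            return o
        return str(o)

    fields = sanitize(dataclasses.asdict(config))
    for incidental in ("out_dir", "log_level"):
        fields.pop(incidental, None)
    blob = json.dumps(fields, sort_keys=True)
    return {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "stages": list(config.stages),
    }


def _write_bundle(bundle: ReportBundle, out_dir: Path) -> None:
    ratios_out = pd.concat([bundle.ratios.meta, bundle.ratios.ratios], axis=1)
    ratios_out.index.name = "peptide_id"
    ratios_out.to_csv(out_dir / "ratios.tsv", sep="\t")
    bundle.calls.map(lambda c: c.value).to_csv(out_dir / "regulation_calls.tsv", sep="\t")
    bundle.counts.to_csv(out_dir / "comparison_counts.tsv", sep="\t")
    if bundle.concurrence is not None:
        (out_dir / "concurrence.json").write_text(json.dumps(bundle.concurrence, indent=1))
    if bundle.enrichments:
        rows = []
        for label, items in bundle.enrichments.items():
            for e in items:
                rows.append(
                    {
                        "comparison": label,
                        "motif": e.pattern.notation(),
                        "constraints": ";".join(f"{off:+d}:{'/'.join(sorted(res))}" for off, res in e.pattern.constraints),
                        "p_value": e.p_value,
                        "score": e.score,
                        "fold_enrichment": e.fold_enrichment,
                        "foreground_count": e.foreground_count,
                    }
                )
        pd.DataFrame(rows).to_csv(out_dir / "motif_enrichment.tsv", sep="\t", index=False)
    if bundle.frequencies:
        rows = []
        for label, freq in bundle.frequencies.items():
            for cls, n in freq.counts.items():
                rows.append(
                    {"comparison": label, "subset": cls.value, "count": n, "proportion": freq.proportions[cls]}
                )
        pd.DataFrame(rows).to_csv(out_dir / "kinase_subset_frequencies.tsv", sep="\t", index=False)
    if bundle.homogeneity is not None:
        bundle.homogeneity.to_csv(out_dir / "homogeneity_tests.tsv", sep="\t", index=False)
    for label, df in bundle.activity.items():
        safe = label.replace("/", "_vs_")
        df.to_csv(out_dir / f"pathway_activity_{safe}.tsv", sep="\t", index=False)
    if bundle.similarity is not None:
        bundle.similarity.to_csv(out_dir / "pathway_similarity.tsv", sep="\t")
    if bundle.clusters is not None:
        bundle.clusters.labels.to_csv(out_dir / "pathway_clusters.tsv", sep="\t")
        (out_dir / "pathway_dendrogram.nwk").write_text(bundle.clusters.newick() + "\n")
    (out_dir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1))
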