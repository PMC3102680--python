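"""Pathway activity scoring from phosphoprotein signature levels.

For a pathway *p* with *k* detected member phosphoproteins, the levels of
those proteins are summed within each replicate, giving per-class replicate
sums P_c1[r], P_c2[r] (three LC-MS/MS runs per class here). The activity
score is a Welch-type t statistic on those sums::

    a_p = (mean(P_c1) − mean(P_c2)) / sqrt(sd(P_c1)²/n_c1 + sd(P_c2)²/n_c2 + ε)

with sample standard deviations and an optional variance floor ε. A
positive score means higher pathway-level phosphorylation in the test
class. Pathways are scored only when at least ``min_members`` member
phosphoproteins are detected (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import PathwayCollection, run_cell_line
from .quant import ComparisonSpec

__all__ = [
    "ActivityConfig",
    "ActivityScore",
    "protein_representative_values",
    "pathway_replicate_level",
    "activity_score",
    "score_all_pathways",
]


@dataclass(frozen=True)
class ActivityConfig:
    min_members: int = 5
    aggregation: str = "mean"  # "mean" | "max_dev": how peptides collapse to a protein
    variance_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.min_members < 1:
            raise ValueError("min_members must be >= 1")
        if self.variance_floor < 0:
            raise ValueError("variance_floor must be >= 0")
        if self.aggregation not in ("mean", "max_dev"):
            raise ValueError("aggregation must be 'mean' or 'max_dev'")


@dataclass
class ActivityScore:
    pathway_id: str
    name: str
    a_p: float
    k: int
    mean_test: float
    mean_reference: float
    sd_test: float
    sd_reference: float
    n_regulated_members: int | None = None


def protein_representative_values(
    peptide_levels: pd.DataFrame,
    protein_of: pd.Series,
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Collapse peptide × run levels to protein × run representative values.

    Default rule: per protein and run, the mean over its detected
    phosphopeptides — this keeps pathway sums comparable across proteins
    with different peptide counts. ``max_dev`` instead keeps the peptide
    with the largest absolute level (the strongest signature).
    """
    levels = peptide_levels.copy()
    groups = levels.groupby(protein_of.reindex(levels.index))
    if aggregation == "mean":
        return groups.mean()
    if aggregation == "max_dev":
        def _max_dev(block: pd.DataFrame) -> pd.Series:
            out = {}
            for col in block.columns:
                vals = block[col].dropna()
                out[col] = np.nan if vals.empty else vals.loc[vals.abs().idxmax()]
            return pd.Series(out)
        return groups.apply(_max_dev)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def _class_runs(run_columns, cell_line: str) -> list:
    runs = [r for r in run_columns if run_cell_line(r) == cell_line]
    if not runs:
        raise KeyError(f"no runs for cell line {cell_line!r}")
    return runs


def pathway_replicate_level(
    protein_matrix: pd.DataFrame,
    members,
    cell_line: str,
) -> tuple[np.ndarray, list[str]]:
    """Per-replicate pathway sums for one class.

    Returns (sums over detected members for each replicate run of the class,
    the detected member list). Missing protein values within a replicate
    contribute 0 to the sum; levels are centered log2 quantities, so an
    absent observation is treated as an average-level one.
    """
    runs = _class_runs(protein_matrix.columns, cell_line)
    detected = sorted(
        m for m in members
        if m in protein_matrix.index and protein_matrix.loc[m, runs].notna().any()
    )
    if not detected:
        return np.zeros(len(runs)), []
    block = protein_matrix.loc[detected, runs]
    return block.sum(axis=0, skipna=True).to_numpy(dtype=float), detected


def activity_score(p_c1, p_c2, variance_floor: float = 0.0) -> float:
    """Welch-form t statistic between two vectors of pathway replicate sums."""
    a = np.asarray(p_c1, dtype=float)
    b = np.asarray(p_c2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("activity_score needs >=2 replicates per class")
    se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size + variance_floor
    if se2 == 0:
        raise ZeroDivisionError("zero pooled variance; set a variance_floor > 0")
    return float((a.mean() - b.mean()) / np.sqrt(se2))


def score_all_pathways(
    protein_matrix: pd.DataFrame,
    pathways: PathwayCollection,
    comparisons: list[ComparisonSpec],
    cfg: ActivityConfig = ActivityConfig(),
    regulated_proteins: dict[str, set[str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Score every admissible pathway for every comparison.

    ``protein_matrix`` is protein × run (log2, normalized, centered).
    Returns one ranked DataFrame per comparison label with columns
    pathway_id, name, k, n_regulated_members, a_p, per-class means/sds,
    sorted by a_p descending (ties broken by pathway id for determinism).
    Pathways with fewer than ``cfg.min_members`` detected members are
    filtered out, not scored.
    """
    out: dict[str, pd.DataFrame] = {}
    for spec in comparisons:
        rows = []
        regulated = (regulated_proteins or {}).get(spec.label, set())
        for pw in sorted(pathways, key=lambda p: p.pathway_id):
            sums_t, det_t = pathway_replicate_level(protein_matrix, pw.members, spec.test)
            sums_r, det_r = pathway_replicate_level(protein_matrix, pw.members, spec.reference)
            detected = sorted(set(det_t) | set(det_r))
            k = len(detected)
            if k < cfg.min_members:
                continue
            a_p = activity_score(sums_t, sums_r, cfg.variance_floor)
            rows.append(
                {
                    "pathway_id": pw.pathway_id,
                    "name": pw.name,
                    "k": k,
                    "n_regulated_members": len(set(detected) & regulated),
                    "a_p": a_p,
                    "mean_test": float(np.mean(sums_t)),
                    "mean_reference": float(np.mean(sums_r)),
                    "sd_test": float(np.std(sums_t, ddof=1)),
                    "sd_reference": float(np.std(sums_r, ddof=1)),
                }
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "pathway_id", "name", "k", "n_regulated_members", "a_p",
                "mean_test", "mean_reference", "sd_test", "sd_reference",
            ],
        )
        if not df.empty:
            df = df.sort_values(["a_p", "pathway_id"], ascending=[False, True]).reset_index(drop=True)
        out[spec.label] = df
    return out
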