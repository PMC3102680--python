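"""Label-free quantitation: internal-standard normalization, replicate QC,
log2 ratios with sentinel codes, 2-fold regulation calling and the
multi-cell-line concurrence filter.

Peptides undetected in one class of a comparison are carried as sentinel
codes rather than imputed: ``+9999`` = detected in the test class only,
``−9999`` = detected in the reference class only, ``NaN`` = in neither.
A sentinel never supports a directional regulation call.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import QuantTable, run_cell_line

__all__ = [
    "SENTINEL_TEST_ONLY",
    "SENTINEL_REF_ONLY",
    "ComparisonSpec",
    "QCConfig",
    "RatioTable",
    "RegulationCall",
    "ReplicateSummary",
    "normalize_to_standard",
    "replicate_cv",
    "summarize_replicates",
    "log2_ratio_table",
    "center_ratios",
    "call_regulation",
    "call_regulation_table",
    "concurrent_regulation",
    "is_sentinel",
]

SENTINEL_TEST_ONLY = 9999.0
SENTINEL_REF_ONLY = -9999.0


def is_sentinel(value: float) -> bool:
    """True for the three non-quantified codes (±9999 and NaN)."""
    return (isinstance(value, float) and math.isnan(value)) or value in (
        SENTINEL_TEST_ONLY,
        SENTINEL_REF_ONLY,
    )


@dataclass(frozen=True)
class ComparisonSpec:
    """A pairwise cell-line comparison, e.g. 3KTR (test) vs 3KT (reference).

    ``regulation_threshold`` is in log2 units; the default 1.0 is the 2-fold
    rule, applied as a closed bound (|log2 ratio| ≥ 1 is regulated).
    """

    test: str
    reference: str
    regulation_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.regulation_threshold <= 0:
            raise ValueError("regulation_threshold must be > 0")

    @property
    def label(self) -> str:
        return f"{self.test}/{self.reference}"


@dataclass(frozen=True)
class QCConfig:
    cv_threshold: float = 0.20
    min_detected_replicates: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.cv_threshold < 1:
            raise ValueError("cv_threshold must lie in (0, 1)")
        if self.min_detected_replicates < 1:
            raise ValueError("min_detected_replicates must be >= 1")


class RegulationCall(enum.Enum):
    UP = "up"
    DOWN = "down"
    UNCHANGED = "unchanged"
    TEST_ONLY = "test_only"
    REFERENCE_ONLY = "reference_only"
    NOT_QUANTIFIED = "not_quantified"


@dataclass
class RatioTable:
    """Per-peptide log2 ratios, one column per comparison label.

    Non-sentinel entries are finite log2(test/reference) values; sentinel
    entries use the codes documented at module level.
    """

    meta: pd.DataFrame
    ratios: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.ratios.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        ordinary = finite[(finite != SENTINEL_TEST_ONLY) & (finite != SENTINEL_REF_ONLY)]
        if not np.isfinite(ordinary).all():
            raise ValueError("non-sentinel ratio entries must be finite")

    @property
    def comparisons(self) -> list[str]:
        return list(self.ratios.columns)

    def ordinary_mask(self) -> pd.DataFrame:
        """Boolean frame: True where the entry is a real log2 ratio."""
        r = self.ratios
        return r.notna() & (r != SENTINEL_TEST_ONLY) & (r != SENTINEL_REF_ONLY)


# ---------------------------------------------------------------------------


def normalize_to_standard(table: QuantTable) -> QuantTable:
    """Divide every abundance by the internal standard's abundance per run.

    The spiked β-casein phosphopeptide tracks run-to-run intensity bias; the
    division cancels any per-run multiplicative scale factor exactly. The
    standard row itself becomes all-ones.
    """
    std_id = table.require_standard()
    std = table.abundance.loc[std_id]
    bad = [run for run, v in std.items() if not (pd.notna(v) and v > 0)]
    if bad:
        raise ValueError(f"internal standard missing or non-positive in runs: {bad}")
    return QuantTable(meta=table.meta.copy(), abundance=table.abundance.div(std, axis=1))


def replicate_cv(values) -> float:
    """Coefficient of variation (sample sd / mean) across detected replicates."""
    arr = np.asarray([v for v in np.ravel(values) if pd.notna(v)], dtype=float)
    if arr.size < 2:
        raise ValueError("replicate_cv needs at least 2 detected values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("replicate_cv undefined for zero mean")
    return float(arr.std(ddof=1) / mean)


@dataclass
class ReplicateSummary:
    """Triplicate-collapsed abundances: one column per cell line.

    ``mean`` is NaN where fewer than ``min_detected_replicates`` runs
    detected the peptide; ``cv`` is NaN where <2 runs detected it; ``clean``
    flags CVs below the QC threshold.
    """

    mean: pd.DataFrame
    cv: pd.DataFrame
    clean: pd.DataFrame
    qc: QCConfig = field(default_factory=QCConfig)


def summarize_replicates(table: QuantTable, qc: QCConfig = QCConfig()) -> ReplicateSummary:
    """Collapse replicate runs to per-(peptide, cell line) mean abundances."""
    groups: dict[str, list[str]] = {}
    for run in table.runs:
        groups.setdefault(run_cell_line(run), []).append(run)
    means, cvs = {}, {}
    for line, runs in groups.items():
        block = table.abundance[runs]
        n_det = block.notna().sum(axis=1)
        mean = block.mean(axis=1, skipna=True).where(n_det >= qc.min_detected_replicates)
        sd = block.std(axis=1, ddof=1, skipna=True)
        cv = (sd / block.mean(axis=1, skipna=True)).where(n_det >= 2)
        means[line], cvs[line] = mean, cv
    mean_df = pd.DataFrame(means)
    cv_df = pd.DataFrame(cvs)
    return ReplicateSummary(mean=mean_df, cv=cv_df, clean=cv_df < qc.cv_threshold, qc=qc)


def log2_ratio_table(
    summary: ReplicateSummary | pd.DataFrame,
    comparisons: list[ComparisonSpec],
    meta: pd.DataFrame | None = None,
) -> RatioTable:
    """log2(test/reference) per peptide, with sentinels for one-sided detection."""
    means = summary.mean if isinstance(summary, ReplicateSummary) else summary
    cols = {}
    for spec in comparisons:
        for line in (spec.test, spec.reference):
            if line not in means.columns:
                raise KeyError(f"cell line {line!r} not present in summary")
        t, r = means[spec.test], means[spec.reference]
        ratio = np.log2(t / r)
        ratio = ratio.where(t.notna() | r.isna(), SENTINEL_REF_ONLY)
        ratio = ratio.where(r.notna() | t.isna(), SENTINEL_TEST_ONLY)
        cols[spec.label] = ratio
    if meta is None:
        meta = pd.DataFrame(index=means.index)
    return RatioTable(meta=meta, ratios=pd.DataFrame(cols))


def center_ratios(table: RatioTable, method: str = "mean") -> RatioTable:
    """Shift each comparison's ordinary ratios so their mean (or median) is 0.

    Removes any residual systematic offset between the two classes after
    internal-standard normalization; sentinel entries are untouched.
    """
    if method not in ("mean", "median"):
        raise ValueError("centering method must be 'mean' or 'median'")
    mask = table.ordinary_mask()
    out = table.ratios.copy()
    for comp in table.comparisons:
        vals = out.loc[mask[comp], comp]
        if vals.empty:
            raise ValueError(f"comparison {comp!r} has no quantified ratios to center")
        shift = vals.mean() if method == "mean" else vals.median()
        out.loc[mask[comp], comp] = vals - shift
    return RatioTable(meta=table.meta.copy(), ratios=out)


def call_regulation(value: float, spec: ComparisonSpec) -> RegulationCall:
    """Fold-change call: up/down at |log2| ≥ threshold; sentinels pass through."""
    if isinstance(value, float) and math.isnan(value):
        return RegulationCall.NOT_QUANTIFIED
    if value == SENTINEL_TEST_ONLY:
        return RegulationCall.TEST_ONLY
    if value == SENTINEL_REF_ONLY:
        return RegulationCall.REFERENCE_ONLY
    if value >= spec.regulation_threshold:
        return RegulationCall.UP
    if value <= -spec.regulation_threshold:
        return RegulationCall.DOWN
    return RegulationCall.UNCHANGED


def call_regulation_table(
    table: RatioTable, specs: list[ComparisonSpec] | None = None, threshold: float = 1.0
) -> pd.DataFrame:
    """Per-peptide, per-comparison :class:`RegulationCall` frame."""
    if specs is None:
        specs = [
            ComparisonSpec(*comp.split("/"), regulation_threshold=threshold)
            for comp in table.comparisons
        ]
    by_label = {s.label: s for s in specs}
    unknown = [s for s in by_label if s not in table.comparisons]
    if unknown:
        raise KeyError(f"comparisons not in ratio table: {unknown}")
    calls = {
        label: table.ratios[label].map(lambda v, s=spec: call_regulation(v, s))
        for label, spec in by_label.items()
    }
    return pd.DataFrame(calls, index=table.ratios.index)


def concurrent_regulation(
    table: RatioTable,
    require: list[str],
    exclude: list[str],
    threshold: float = 1.0,
    protein_column: str = "gene_symbol",
) -> dict[str, list[str]]:
    """Proteins regulated in the same direction in every *require* comparison
    but not concurrently so in any *exclude* comparison.

    A protein qualifies when at least one of its phosphopeptide rows is
    called up (or down) in all *require* comparisons, while in every
    *exclude* comparison that row is unchanged, discordant in direction, or
    sentinel-coded. Returns ``{"up": [...], "down": [...]}`` with sorted,
    de-duplicated protein identifiers.
    """
    calls = call_regulation_table(table, threshold=threshold)
    for comp in list(require) + list(exclude):
        if comp not in calls.columns:
            raise KeyError(f"unknown comparison label {comp!r}")
    result: dict[str, set[str]] = {"up": set(), "down": set()}
    for direction, call in (("up", RegulationCall.UP), ("down", RegulationCall.DOWN)):
        ok = pd.Series(True, index=calls.index)
        for comp in require:
            ok &= calls[comp] == call
        for comp in exclude:
            ok &= calls[comp] != call
        result[direction].update(table.meta.loc[ok, protein_column])
    return {d: sorted(v) for d, v in result.items()}
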