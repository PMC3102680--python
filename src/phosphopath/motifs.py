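"""Phosphosite sequence windows, kinase-consensus motif classes, iterative
binomial (motif-x style) enrichment, and kinase-subset frequency comparison.

Windows are 13-mers spanning positions −6…+6 around a phosphorylated S/T/Y,
padded with ``_`` beyond the protein termini. Sites are classed by consensus:
proline-directed ([pS/T]-P, the MAPK/CDK/GSK signature), basophilic
(R-X-X-[pS], PKA/PKC-type), acidophilic (acidic residues C-terminal to the
site, CK2-type), or other. When a window matches several consensi the fixed
precedence proline-directed > basophilic > acidophilic assigns the primary
class; dual motifs (e.g. R-X-X-[pS]-P) do occur and all matches are
retrievable via :func:`matching_classes`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AMINO_ACIDS",
    "FLANK",
    "PAD",
    "MotifClass",
    "MotifPattern",
    "EnrichmentConfig",
    "MotifEnrichment",
    "extract_window",
    "window_from_marked_peptide",
    "classify_window",
    "matching_classes",
    "motifx_enrich",
    "subset_frequencies",
    "homogeneity_test",
    "DEFAULT_CLASS_RULES",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
FLANK = 6
PAD = "_"
PHOSPHO_RESIDUES = frozenset("STY")


class MotifClass(enum.Enum):
    PROLINE_DIRECTED = "proline_directed"
    BASOPHILIC = "basophilic"
    ACIDOPHILIC = "acidophilic"
    OTHER = "other"


@dataclass(frozen=True)
class MotifPattern:
    """Conjunction of (offset, allowed residues) constraints around the site.

    Offsets are relative to the phosphosite (never 0); a window matches when
    every constrained offset holds one of the allowed residues.
    """

    constraints: tuple[tuple[int, frozenset[str]], ...]

    def __post_init__(self) -> None:
        for offset, residues in self.constraints:
            if not -FLANK <= offset <= FLANK or offset == 0:
                raise ValueError(f"offset {offset} outside ±{FLANK} or zero")
            if not residues:
                raise ValueError("empty residue set in motif constraint")

    @classmethod
    def of(cls, **kw) -> "MotifPattern":  # MotifPattern.of(p1="P", m3="R")
        constraints = []
        for key, residues in kw.items():
            sign = {"p": 1, "m": -1}[key[0]]
            constraints.append((sign * int(key[1:]), frozenset(residues)))
        return cls(tuple(sorted(constraints)))

    def matches(self, window: str) -> bool:
        center = len(window) // 2
        return all(window[center + off] in res for off, res in self.constraints)

    def extended(self, offset: int, residues: frozenset[str]) -> "MotifPattern":
        return MotifPattern(tuple(sorted(self.constraints + ((offset, residues),))))

    def notation(self) -> str:
        """Compact glyph string, center shown as ``*``: ``"...R..*P......"``."""
        cells = ["."] * (2 * FLANK + 1)
        cells[FLANK] = "*"
        for off, res in self.constraints:
            cells[FLANK + off] = res.__iter__().__next__() if len(res) == 1 else "[" + "/".join(sorted(res)) + "]"
        return "".join(cells)


#: class → list of alternative patterns; a class matches if any alternative does.
DEFAULT_CLASS_RULES: dict[MotifClass, tuple[MotifPattern, ...]] = {
    MotifClass.PROLINE_DIRECTED: (MotifPattern.of(p1="P"),),
    MotifClass.BASOPHILIC: (MotifPattern.of(m3="R"),),
    MotifClass.ACIDOPHILIC: (MotifPattern.of(p1="DE"), MotifPattern.of(p3="E")),
}

CLASS_PRECEDENCE = (MotifClass.PROLINE_DIRECTED, MotifClass.BASOPHILIC, MotifClass.ACIDOPHILIC)


def extract_window(sequence: str, position: int, flank: int = FLANK) -> str:
    """13-mer around the 1-based *position*; ``_`` pads beyond the termini."""
    if not 1 <= position <= len(sequence):
        raise ValueError(f"site position {position} outside sequence of length {len(sequence)}")
    center = sequence[position - 1]
    if center not in PHOSPHO_RESIDUES:
        raise ValueError(f"residue at position {position} is {center!r}, not S/T/Y")
    left = sequence[max(0, position - 1 - flank) : position - 1]
    right = sequence[position : position + flank]
    return PAD * (flank - len(left)) + left + center + right + PAD * (flank - len(right))


def window_from_marked_peptide(peptide: str, which: int = 0, flank: int = FLANK) -> str:
    """Window from a peptide carrying ``p``-prefixed phosphosites.

    ``which`` selects among multiple marked sites (0 = first). The peptide's
    own termini are padded, so windows extracted here match
    :func:`extract_window` run on the full protein only when the peptide
    covers the ±flank context.
    """
    bare, positions = parse_marked_peptide(peptide)
    if not positions:
        raise ValueError(f"no phospho marker in peptide {peptide!r}")
    return extract_window(bare, positions[which], flank=flank)


def parse_marked_peptide(peptide: str) -> tuple[str, list[int]]:
    """Strip ``p`` markers; return the bare sequence and 1-based site positions."""
    bare, positions = [], []
    i = 0
    while i < len(peptide):
        ch = peptide[i]
        if ch == "p" and i + 1 < len(peptide) and peptide[i + 1] in PHOSPHO_RESIDUES:
            positions.append(len(bare) + 1)
            i += 1
            continue
        bare.append(ch)
        i += 1
    return "".join(bare), positions


def matching_classes(
    window: str, rules: dict[MotifClass, tuple[MotifPattern, ...]] = DEFAULT_CLASS_RULES
) -> list[MotifClass]:
    """All consensus classes the window matches, in precedence order."""
    _check_window(window)
    return [
        cls for cls in CLASS_PRECEDENCE if any(p.matches(window) for p in rules.get(cls, ()))
    ]


def classify_window(
    window: str, rules: dict[MotifClass, tuple[MotifPattern, ...]] = DEFAULT_CLASS_RULES
) -> MotifClass:
    """Primary consensus class under the fixed precedence; OTHER if none match."""
    matched = matching_classes(window, rules)
    return matched[0] if matched else MotifClass.OTHER


def _check_window(window: str) -> None:
    if len(window) != 2 * FLANK + 1:
        raise ValueError(f"window must have length {2 * FLANK + 1}")
    if window[FLANK] not in PHOSPHO_RESIDUES:
        raise ValueError("window center must be S/T/Y")


# ---------------------------------------------------------------------------
# motif-x style iterative enrichment


@dataclass(frozen=True)
class EnrichmentConfig:
    p_threshold: float = 1e-10
    min_occurrences: int = 20
    max_depth: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")


@dataclass
class MotifEnrichment:
    """One extracted motif with the binomial p at each constraint fixation."""

    pattern: MotifPattern
    p_value: float            # p of the final fixation step
    step_p_values: tuple[float, ...]
    fold_enrichment: float    # fg matched fraction / bg matched fraction at fixation
    foreground_count: int
    foreground_size: int

    @property
    def score(self) -> float:
        """motif-x style score: sum of −log10(p) over fixation steps."""
        return float(sum(-math.log10(max(p, 5e-324)) for p in self.step_p_values))


def binomial_tail(k: int, n: int, p0: float) -> float:
    """P(X ≥ k) for X ~ Binomial(n, p0)."""
    return float(stats.binom.sf(k - 1, n, p0))


def motifx_enrich(
    foreground: list[str], background: list[str], cfg: EnrichmentConfig = EnrichmentConfig()
) -> list[MotifEnrichment]:
    """Iteratively extract over-represented (offset, residue) motifs.

    Inner loop: for every unconstrained offset and residue, compute the
    binomial tail probability of the foreground count given the background
    frequency; fix the most significant pair if p < ``p_threshold`` and the
    count ≥ ``min_occurrences``; restrict both sets to matching windows and
    repeat until no pair qualifies (or ``max_depth`` constraints). Outer
    loop: emit the motif, remove its matching windows from foreground and
    background, and search for the next motif until none is found.

    The background should contain the plausible proteome context (by default
    the caller passes all quantified sites, not only regulated ones).
    """
    if not foreground:
        raise ValueError("motifx_enrich requires a non-empty foreground")
    for w in foreground + background:
        _check_window(w)
    fg = list(foreground)
    bg = list(background)
    results: list[MotifEnrichment] = []
    fg_size_initial = len(fg)
    while fg and bg:
        motif = _grow_motif(fg, bg, cfg)
        if motif is None:
            break
        pattern, step_ps, fold, fg_count = motif
        results.append(
            MotifEnrichment(
                pattern=pattern,
                p_value=step_ps[-1],
                step_p_values=tuple(step_ps),
                fold_enrichment=fold,
                foreground_count=fg_count,
                foreground_size=fg_size_initial,
            )
        )
        fg = [w for w in fg if not pattern.matches(w)]
        bg = [w for w in bg if not pattern.matches(w)]
    return results


def _grow_motif(fg, bg, cfg):
    """Greedy constraint fixing for one motif; None when nothing qualifies."""
    pattern = MotifPattern(())
    step_ps: list[float] = []
    fold = float("nan")
    cur_fg, cur_bg = list(fg), list(bg)
    while len(pattern.constraints) < cfg.max_depth:
        best = None
        used = {off for off, _ in pattern.constraints}
        n_fg, n_bg = len(cur_fg), len(cur_bg)
        for offset in range(-FLANK, FLANK + 1):
            if offset == 0 or offset in used:
                continue
            idx = FLANK + offset
            fg_counts: dict[str, int] = {}
            bg_counts: dict[str, int] = {}
            for w in cur_fg:
                fg_counts[w[idx]] = fg_counts.get(w[idx], 0) + 1
            for w in cur_bg:
                bg_counts[w[idx]] = bg_counts.get(w[idx], 0) + 1
            for residue in AMINO_ACIDS:
                k = fg_counts.get(residue, 0)
                b = bg_counts.get(residue, 0)
                if k < cfg.min_occurrences or b == 0:
                    continue  # background must support the context
                p0 = b / n_bg
                p = binomial_tail(k, n_fg, p0)
                if p >= cfg.p_threshold:
                    continue
                cand = (p, -k, offset, residue)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        p, neg_k, offset, residue = best
        pattern = pattern.extended(offset, frozenset(residue))
        step_ps.append(p)
        cur_fg = [w for w in cur_fg if pattern.matches(w)]
        cur_bg = [w for w in cur_bg if pattern.matches(w)]
        fg_frac = len(cur_fg) / len(fg)
        bg_frac = len(cur_bg) / len(bg)
        fold = fg_frac / bg_frac if bg_frac > 0 else float("inf")
    if not pattern.constraints:
        return None
    return pattern, step_ps, fold, len(cur_fg)


# ---------------------------------------------------------------------------
# kinase-subset frequencies


@dataclass
class SubsetFrequencies:
    counts: dict[MotifClass, int]
    proportions: dict[MotifClass, float]

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[c] for c in MotifClass], dtype=float)

    @property
    def modal_class(self) -> MotifClass:
        return max(MotifClass, key=lambda c: self.counts[c])


def subset_frequencies(classes: list[MotifClass]) -> SubsetFrequencies:
    """Counts and proportions of sites per kinase subset (4 consensus classes)."""
    if not classes:
        raise ValueError("subset_frequencies requires a non-empty class list")
    counts = {c: 0 for c in MotifClass}
    for c in classes:
        counts[c] += 1
    total = len(classes)
    return SubsetFrequencies(counts=counts, proportions={c: n / total for c, n in counts.items()})


def homogeneity_test(freq_a, freq_b) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity on a 2×k count table.

    Categories with zero column totals are dropped before testing (their
    expected counts would be zero). Returns (statistic, dof, p).
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("homogeneity_test requires two equal-length count vectors")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("homogeneity_test requires non-zero count vectors")
    table = np.vstack([a, b])
    table = table[:, table.sum(axis=0) > 0]
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)
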