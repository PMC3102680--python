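# Methods

## Quantitation model and normalization

The quantitation unit is the phosphopeptide: a tryptic peptide with one or
more phosphorylated S/T/Y residues, observed as a nonnegative abundance per
LC-MS/MS run or missing. Runs are grouped into classes (cell lines) with
three replicate runs each. A spiked β-casein phosphopeptide
(FQpSEEQQQTEDELQDK) serves as internal standard: dividing every abundance by
the standard's abundance in the same run removes per-run multiplicative
intensity bias exactly. This is the only between-run normalization; it is
followed, at the ratio level, by per-comparison centering (mean by default,
median selectable) to absorb any residual systematic offset between two
classes. Centering uses the mean because the log2 ratios of the bulk
(unregulated) peptides are approximately symmetric under the noise model;
with heavy contamination by true effects the median option is safer.

Replicate summaries use the mean over detected runs, requiring detection in
at least 2 of 3 replicates (below that, the class value is missing). The QC
statistic is the coefficient of variation, sample sd / mean, flagged against
a 0.20 threshold. The detection rule is a design choice: most peptides in
the emulated design appear in all three runs, and requiring 2 of 3 keeps
one-off identifications out of ratios without discarding real signal.

Ratios are log2(test/reference). Peptides detected in exactly one class are
not imputed; they carry sentinel codes (+9999 test-only, −9999
reference-only, NaN neither) through every downstream table. Regulation is
a pure fold-change call: up/down at |log2| ≥ 1.0 (closed bound, i.e. 2-fold
exactly counts), no replicate-variance criterion. Sentinels map to their own
call categories and never support a directional call. The concurrence
filter asks, per protein, whether at least one site row is called in the
same direction in every "require" comparison while every "exclude"
comparison shows that row as unchanged, direction-discordant, or
sentinel-coded.

## Motif analysis

Site windows are 13-mers (±6 residues) around the phosphosite, `_`-padded
beyond protein termini. Consensus classes are pattern rules over window
offsets: proline-directed = P at +1; basophilic = R at −3; acidophilic =
D/E at +1 or E at +3; other = none of these. The acidophilic wildcard
notation in the source material is ambiguous, so the rule set is data
(`MotifPattern` lists) rather than code and can be overridden. Windows
matching several consensi (e.g. R-X-X-[pS]-P) are assigned by the fixed
precedence proline > basophilic > acidophilic — proline-directed kinases
have the strictest positional requirement — and all matches remain
retrievable.

Enrichment follows the iterative motif-x scheme. For each candidate
(offset, residue) the significance is the exact binomial tail
P(X ≥ k | n, p₀), where k is the foreground count, n the current foreground
size and p₀ the background frequency at that offset. The most significant
pair is fixed when p < 10⁻¹⁰ and k ≥ 20; both sets are then restricted to
matching windows and the search repeats (up to 5 constraints per motif).
When nothing more qualifies, the motif is emitted with its per-step
p-values, matching windows are removed from both sets, and the outer search
restarts. Candidates whose background count is zero are skipped: without
background support the frequency p₀ is undefined and such a pattern cannot
be scored. The recommended background is all quantified windows of the
comparison, not only regulated ones.

Kinase-subset frequency vectors (counts over the four classes) are compared
between cell lines with the Pearson chi-square homogeneity test on the 2×k
table, without continuity correction; categories with zero column totals
are dropped first.

## Pathway activity

Peptide levels for activity scoring are log2 of internal-standard-normalized
abundances. Proteins collapse their peptides by the per-replicate mean
(keeping pathway sums comparable across proteins with different peptide
counts; a max-|level| alternative is available). For a pathway, member
protein levels are summed within each replicate; the activity score is the
Welch-form t statistic between the test- and reference-class replicate sums,
with sample standard deviations, n = 3 per class, and an optional variance
floor ε (default 0) for degenerate zero-variance inputs. With equal
replicate counts this coincides with the pooled two-sample t when class
variances are equal. Only pathways with at least `min_members` (default 5)
detected member phosphoproteins are scored; missing protein values within a
replicate contribute 0 to the sum, which under centered log2 levels treats
an absent observation as average-level. Scores are reported ranked and
signed; no significance cutoff is imposed — the score is a ranking
statistic, and calibrating it would require a null model that the replicate
structure (n = 3) cannot support well.

## Pathway functional clustering

Annotations are closed under is_a ancestors (other relation types are
ignored on ingest), excluding namespace roots so that universally shared top
terms never inflate similarity. The default pairwise similarity between two
pathways is the Jaccard index of the unions of their members' propagated
term sets, computed per namespace and averaged over namespaces present in
either pathway. A best-match-average variant (per-term ancestor-set Jaccard,
averaged over best matches both ways) is selectable; the similarity function
is a strategy slot precisely because reasonable alternatives exist.

Clustering is hierarchical agglomerative average linkage. The default
distance is 1 − Pearson correlation of two pathways' similarity-matrix rows
with the two self-columns excluded pairwise (profile correlation); a direct
1 − similarity distance is available. The flat partition is the dendrogram
cut at distance 1 − threshold (default threshold 0.5), so raising the
threshold can only refine the partition. Pathway ids are sorted before
linkage, making tie-breaks deterministic. Dendrograms export to Newick.

## Synthetic data generator

The generator emulates: five cell lines (3KT reference; 3KTR, A549, H322,
H1299) × three runs; log2-normal abundances (baseline N(20, 2) in log2
units); per-run multiplicative scale factors 2^U(−1,1); replicate noise
N(0, sd) in log2 with default sd 0.25 (replicate CVs near the 20% QC
bound); a standard row equal to run_scale × 2¹⁸; planted per-peptide log2
effects (explicit map, or a drawn set with configurable size, magnitude and
sign mix) and per-pathway effects applied to all member-protein peptides in
designated lines; class-exclusive peptides fully absent in one line
(becoming sentinels downstream); site windows drawn from a motif mix
defaulting to 60/20/10/10 percent proline-directed/basophilic/acidophilic/
other, matching a site population dominated by proline-directed contexts;
20 pathways of 10 members drawn from two protein communities; and a rooted
is_a tree (depth 4, branching 3) whose first two depth-1 subtrees define
the communities' annotation leaf pools, with 10% cross-community annotation
noise. Proteins are concatenations of their 13-mer site windows, so
FASTA-extracted windows equal the generated ones. Everything derives from a
single seed; explicitly supplied scale factors do not perturb the stream.

What it does **not** emulate: spectra, retention-time alignment, missed
cleavages, peptide misidentification, intensity-dependent missingness
(missingness here is class-structured or absent), correlated noise between
co-eluting peptides, and shared peptides between proteins. Passing recovery
tests therefore demonstrates correctness of the inference chain under the
stated noise model, not robustness to every artifact of real LC-MS/MS data.

## Problem sizes and numerics used in the test suite

Recovery checks run at the generator defaults (200 proteins, ≈440
peptides, 15 runs): regulation recovery with ±2 log2 effects at noise sd
0.1; pathway recovery over 100 seeds with a +1 log2 effect on one 10-member
pathway among 20 at noise sd 0.25; null-tail and null-activity checks at
520 proteins / 200 pathways. Binomial tails are validated against exact
rational summation (relative error < 1e-9), the chi-square against a
first-principles computation, and the activity score against its closed
form. Sentinel codes are compared exactly; ratio algebra to 1e-9.

## Known limitations

- The activity score's exact published algebra was only available in
  figure form; the implemented per-replicate-sum Welch t is the most direct
  reading and is isolated behind `activity_score` so an alternative
  aggregation can be swapped in.
- Multi-phosphosite peptides are carried as single rows sharing one ratio.
- Site positions are taken as 1-based labels on the given protein sequence;
  isoform mapping is out of scope.
- GMT/annotation/OBO ingestion is deliberately minimal (is_a only, 2-column
  annotations), sufficient for the similarity computation but not a general
  GO toolchain.
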