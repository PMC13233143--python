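# Methods

## Problem setting

Promoters of tissue-specific (TSp) transcripts carry sequence features —
transcription-factor binding motifs and their spatial arrangement around
the transcription start site (TSS) — that distinguish them both from
random genomic background and from promoters of broadly expressed genes.
`promotif` implements the interpretability side of this problem: given a
binary promoter classifier that exposes [CLS]→token attention, extract
the motifs the classifier relies on, test them statistically, and locate
them relative to the TSS.

Two classifier designs are distinguished because they answer different
questions. A model trained against **random non-promoter windows**
("Model A") learns general promoter biology; a model trained against
**GC- and repeat-matched genomic nulls** ("Model B") cannot lean on base
composition and is forced toward tissue-specific grammar. Motifs
significant for B but absent from A (B ∩ Aᶜ) are the tissue-specific
candidates.

## Dataset construction

Windows are anchored at the TSS with configurable upstream/downstream
extents (defaults 1.5 kb / 0.5 kb; the classifiers this package is built
for work at 2–4 kb). All coordinates are 0-based half-open; minus-strand
windows are reverse-complemented so each stored sequence reads 5′→3′ in
transcription orientation and "upstream" means upstream of transcription.
Out-of-bounds windows are errors, never clipped: silent truncation would
break the length invariant every downstream coordinate computation
relies on.

Expression groups follow the TransTEx vocabulary (TSp, TEn, Wide, Low,
Null) and are an *input*; deriving them from expression matrices is out
of scope. Label 1 is TSp-in-target-tissue; the negative groups are
configurable (default: all four non-TSp groups). Classes are kept 1:1 by
construction of the negative sets.

Model A negatives are uniform random genomic windows rejected against an
exclusion interval set (typically all annotated promoter windows).
Negatives may overlap one another — only disjointness from the exclusion
set is enforced, which matches how such backgrounds are usually drawn.
Model B negatives match each positive within `gc_tolerance` (default
0.02) and `repeat_tolerance` (default 0.05), where repeat content is
operationalized as the soft-masked (lowercase) fraction of the window.
These tolerances are package defaults, chosen tight enough that a
composition-based classifier gains nothing, and are fully configurable.
Unmatchable positives are reported and skipped rather than failing the
run, since a handful of extreme-GC promoters should not abort dataset
construction.

Redundancy reduction keeps one representative per cluster of
near-identical sequences. If an external `mmseqs`-style tool is
configured it is invoked with the 0.8 identity / 0.8 coverage thresholds;
otherwise an internal greedy clusterer assigns each sequence (processed
longest-first) to the first representative whose best ungapped identity
over a ±20 bp offset band reaches the identity threshold. The internal
metric is substitution-oriented; indel-divergent duplicates are beyond
its reach, which is acceptable for promoter windows extracted from a
single assembly. Splits are stratified per class with largest-remainder
rounding (80/10/10 train/validation/test) and are deterministic under the
split seed.

## Attention provider contract

Downstream code consumes exactly three capabilities — `tokenize`,
`attend` (per-layer, per-head softmaxed [CLS]→token rows plus token
character spans) and `predict` — and never inspects model internals.
Rows are accepted as already softmaxed; whether a transformer's attention
was taken pre- or post-residual renormalization is deliberately outside
the contract. Layer indices are 1-based.

The toy model makes the pipeline testable under known ground truth: token
logits are `κ · overlap_fraction(token, planted interval)` plus optional
seeded Gaussian noise, softmaxed per head. κ = 0 (no noise) gives uniform
rows; attention mass on planted tokens increases monotonically with κ.
Its default prediction rule is "label 1 iff anything is planted", which
is the natural test double for a classifier that has learned the planted
feature. A second mode (`predict="label"`) returns the true label — an
idealized, always-correct classifier. This matters for calibration
experiments: conditioning on the *correctness* of a planting-driven
classifier under an equal-plant-rate null retains exactly the
positives-with-motif and negatives-without, which manufactures enrichment
out of selection alone. The null calibration therefore runs with the
ideal classifier, making the correctness filter a no-op and leaving the
tested set unbiased; the signal-bearing recovery experiment keeps the
planting-driven rule and the filter.

Interpretation uses correctly predicted sequences only (the filter
above): attention from misclassified sequences explains the mistake, not
the class.

## Motif discovery

Per sequence and layer, head-averaged [CLS] attention `α_j` is
max-normalized to `ŝ_j = α_j / max(α)` so every sequence has peak score
exactly 1 regardless of length or attention sharpness. Head-sum and
head-mean aggregation differ by the constant head count and give
identical `ŝ`; this is asserted in tests. Layer informativeness is scored
by `Sp = (max ŝ − μ)/σ` with the *sample* standard deviation (a
convention applied consistently here and in the SHAP summaries; it only
rescales constants). σ = 0 (uniform attention) maps to Sp = 0.

The default layer combination averages the middle layers and the final
layer (for a 12-layer encoder: mean(ŝ₅,ŝ₆,ŝ₇) averaged with ŝ₁₂, then
re-normalized), with equal weights since no principled weighting presents
itself; single-layer and top-Sp strategies are available, and small toy
models fall back to their middle third plus final layer.

Candidate selection marks tokens with `ŝ_j > μ` and `ŝ_j > 2·min(ŝ)`
(both strict, μ and min per sequence — consistent with the per-sequence
normalization) and concatenates maximal runs of marked tokens into
regions; regions shorter than 4 bp are dropped. Run concatenation is
required because informative features regularly span adjacent tokens;
single-token selection would fragment multi-token motifs. When attention
is near-uniform, `2·min(ŝ)` approaches or exceeds 1 and nothing passes —
by design, a sequence with no attention structure contributes no
candidates. Candidates are harvested from positive sequences (the class
being interpreted) by default.

Counting uses a hand-built Aho–Corasick automaton (goto/fail/output),
scanning each sequence once for all motifs and recording every
overlapping occurrence. Presence/absence — not occurrence count — feeds
the enrichment test. Motifs with fewer than three total instances are
discarded before testing; sequence-unique candidate regions (runs that
include sequence-specific flanking bases) are thereby removed, which both
reflects the "at least three instances" rule and keeps the multiple-
testing burden meaningful.

Enrichment uses the hypergeometric upper tail `P(X ≥ k)` for k positive
carriers among n carriers when K of N sequences are positive. The pmf
`P(X = k)` is exposed separately; the tail, not the pmf, is the
over-representation p-value, because the pmf is not monotone in
enrichment. Multiple testing is Benjamini–Hochberg at α = 0.01 (the
default reading of "FDR correction"). Both statistics are delegated to
scipy/statsmodels and verified against exhaustive-enumeration and
brute-force step-up oracles in the test suite.

Significant motifs are merged greedily by best ungapped overlap:
processing longest-first (ties lexicographic), a motif joins a cluster
when its best-offset match count reaches 0.8 × the shorter length; the
cluster consensus extends by union at the best offset with majority base
at conflicts (ties to the alphabetically first base; offset ties to the
smallest offset). The pass is iterated to a fixpoint so merging is
idempotent. The 0.8 threshold is a package default — one mismatch in
five — and configurable. Merging happens after significance testing;
a merged motif inherits the union of member instances and the minimum
member p/q.

±12 bp windows around instance centers (floor midpoint; clipped at
sequence bounds) are exported as FASTA for downstream de-novo motif
tools. The B ∩ Aᶜ difference is exact on motif strings by default, with
a similarity mode that also excludes B motifs whose best ungapped overlap
with any A motif reaches the merge threshold.

## SHAP attribution

The classifier is a cooperative game over tokens: coalition value =
positive-class logit with all non-coalition tokens masked, baseline =
everything masked. Kernel SHAP solves the Shapley-kernel weighted least
squares with the local-accuracy constraint eliminated analytically; when
the proper coalitions fit in the budget they are fully enumerated and the
estimate is exact (verified against an independent permutation/enumeration
oracle to 1e-6). Sampling draws coalition sizes with probability
proportional to the kernel mass of the size class, making uniform WLS
weights correct. The coalition budget and background are unspecified
territory in practice; defaults (2048 coalitions) are exposed in config.

Summaries group attributions by unique token text across sequences.
"Absolute mean SHAP" is ambiguous between mean(|φ|) and |mean(φ)|; the
table carries both (`abs_mean_shap`, `mean_abs_shap_signed`), with
mean(|φ|) — the usual SHAP importance — as the ranking key. The 95% CI is
the normal approximation `1.96·σ/√n` exactly as conventionally reported,
without a t-correction. Tokens with fewer than `min_count` (default 5)
occurrences are excluded as noise. Rankings sort descending with
lexicographic tie-break, so they are invariant to input row order.

## Positional analysis

Window-local instance coordinates map to genomic coordinates strand-
awarely (minus-strand instances reflect: `genomic_start = tss + upstream
− instance_end`) and to the signed TSS distance `instance_start −
upstream`, which is strand-independent because windows are stored in
transcription orientation — profiles from both strands pool directly.

Attention is profiled in 100 bp bins `[edge, edge+100)` anchored at the
TSS (an exact-edge distance belongs to the right bin); the three-bin
rolling average is centered with edge bins averaged over their available
neighbors, and empty bins are *absent*, not zero-filled — imputing zero
attention where no motif occurs would fabricate signal. Distance
distributions use a Gaussian KDE with Scott's bandwidth over
[min − 3h, max + 3h]; the curve integrates to 1 within 1e-3.

Peak-overlap enrichment compares the proportion of motif regions
overlapping ≥ 1 reference peak against the same proportion for background
regions with a one-sided Fisher exact test; an infinite odds ratio
(motifs overlap, background never) is flagged rather than truncated.
Region sets are ranked by overlap proportion; this is an interpretation —
the ranking statistic used against large peak compendia is not uniquely
standardized — and is isolated in one function.

## Synthetic data

The generator is the package's test bed and defines its calibration
conditions. Background sequence is i.i.d. with GC control (a
higher-order Markov background is deliberately not the default — i.i.d.
suffices for calibrating the enrichment machinery, and structured
backgrounds would entangle calibration with background modeling). The
planted motif (default `GGCACGTG`, an 8 bp E-box-like word) is
substituted in place, preserving sequence length so window arithmetic
stays exact; plant positions follow Gaussian(−150 bp, 50 bp) relative to
the TSS (resampled into bounds) or uniform. Defaults are 200 positives /
200 negatives, 2 kb windows (1.5 kb up / 0.5 kb down), plant rates
0.8 / 0.05.

What passing tests show — and what they do not: recovery and calibration
results demonstrate that the *pipeline machinery* is correct (scores,
matching, testing, merging, coordinates), under an attention model whose
concentration on the signal is controlled. They do not certify that any
particular trained transformer attends to biological motifs, nor do they
reproduce performance numbers on real tissue promoter sets, which depend
on trained models, real genomes and external databases.

## Numerical and design notes

- All sampling is through `numpy.random.default_rng` with explicit seeds;
  per-sequence toy-model streams derive from (model seed, CRC32 of the
  sequence id) so record order never matters.
- The toy tokenizer default is fixed k = 8 non-overlapping segmentation —
  BPE-scale token length without a learned vocabulary; greedy
  longest-match vocabulary tokenization is available and must include
  single nucleotides to guarantee totality.
- Hypergeometric inputs are validated (k ≤ min(K, n), n ≤ N, table
  feasibility); inconsistent counts raise instead of returning a wrong
  tail.
- `fisher_exact`, `gaussian_kde`, `hypergeom` and BH correction come from
  scipy/statsmodels; every one is cross-checked against an independent
  enumeration oracle in the test suite rather than trusted blindly.
- Stratified splitting uses largest-remainder apportionment so per-class
  counts match the ratios within ±1 at any class size ≥ 3.

## Known limitations

- The internal redundancy clusterer is ungapped and band-limited; heavy
  indel redundancy requires the external clustering tool.
- Kernel SHAP on long sequences (hundreds of tokens) is expensive; the
  CLI attributes a configurable subset of records by default.
- The matched-null sampler is rejection-based; extreme-composition
  positives in small genomes exhaust the attempt budget and are reported
  unmatched rather than matched approximately.
- Merged-motif p/q values are inherited minima over members, not
  recomputed for the consensus string (the consensus need not occur
  verbatim in any sequence).
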