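# Methods

`isomirarm` reimplements, as a tested library, a small-RNA sequencing
analysis of miRNA arm selection and isomiR composition in paired libraries
(the motivating use case is a normal/tumor tissue pair).  This note records
the models, parameter choices and numerical conventions, and what the
synthetic data can and cannot demonstrate.

## Read preprocessing

Small-RNA inserts are shorter than the sequencing read, so a genuine insert
is followed by (part of) the 3' adapter.  `trim_adapter` keeps the prefix
before the leftmost exact occurrence of either the full adapter or an
adapter prefix of at least `min_overlap` (default 6) nucleotides reaching
the read's 3' end; reads without adapter evidence are discarded as
not-clean.  Matching is exact with no mismatches — deterministic and easy
to verify; sophisticated error-tolerant adapter trimming is out of scope,
and pre-collapsed `(sequence, count)` TSV input bypasses the stage
entirely.  Clean reads are restricted to 18–25 nt (the mature-miRNA length
envelope), collapsed to unique sequences, and unique reads observed fewer
than 2 times are dropped.  Length filtering is applied before the count
filter; counts are tallied on length-passed reads.  FASTQ quality scores
are ignored.

## Mapping with 3' trim rescue

Reads are mapped to pre-miRNA hairpins by exact substring search on the
given strand only (small-RNA protocols are stranded).  No mismatches are
allowed anywhere: this is the ambiguity control that makes near-identical
paralogous matures distinguishable.  Because non-templated nucleotides
(mostly A and U) are commonly appended to mature 3' ends, a read with zero
exact hits anywhere in the reference is retried after removing its
3'-terminal nucleotide, one base at a time, while the remainder is at
least 18 nt; the search stops at the first (longest) length with a hit and
the removed suffix is kept as the read's addition fragment.  Trimming is
only attempted for reads that are otherwise unmappable — it exists to
rescue reads, not to shorten mappable ones — and consequently an appended
base that coincidentally matches the template is never recognized as an
addition (see the simulator section).

A read matching k loci contributes its full count to each locus by
default; `split_multihits` divides the count by k, which preserves global
read-count conservation in the presence of paralogs.

## isomiR assignment and opposite-arm detection

A mapped read is an isomiR of a mature annotation on the same hairpin when
its start position is within ±2 nt and its end position within ±5 nt of
the annotated span; larger shifts are treated as random matches.  Offsets
are read coordinate minus mature coordinate, printed with explicit sign;
the (0,0) isomiR is the reference form.  When two annotations accept the
same read, the smaller |start offset| wins (ties: smaller |end offset|,
then the 5p arm) and a warning is logged.  A mature miRNA's expression is
the sum of its isomiR counts.

Arm labels follow the midpoint rule: a span whose midpoint lies strictly
in the 5' half of the hairpin (`(start+end)/2 < (length+1)/2`) is 5p,
otherwise 3p.  An exact tie falls to 3p and is flagged; a mature equal to
the whole hairpin is rejected.

Hairpins annotated on a single arm are screened for an unannotated
opposite-arm product: reads that failed every offset window and whose
midpoint lies on the unannotated arm are clustered, the most abundant
read's span defines the detected mature (discarded if its defining count
is below 2), and the remaining reads are re-assigned against it.
Detection runs per library and detections are cross-tabulated (exclusive
to either library, or shared); when both libraries detect the same arm
with different spans, the span of the higher-count defining read is used.
The most-abundant-read convention for the reference span is a design
choice; reference forms in real data are frequently not the most abundant
isomiR, so detected spans should be treated as operational anchors, not
annotations.

## Arm-selection ratios

For each hairpin the per-arm expression in libraries N and T gives the
within-library ratios `Ratio_N53p = N5p/N3p` and `Ratio_T53p = T5p/T3p`;
the fold change is the larger ratio divided by the smaller (this max/min
definition reproduces, row for row, the published ten-row worked example
bundled in `isomirarm.examples`).  Hairpins with any of the four counts
below 10 are excluded, and fold change strictly greater than 3 flags a
significant arm-selection difference.  Ratios use raw within-library
counts: a within-library ratio is invariant under any per-library scaling,
so depth normalization cannot change it.  Ratios are carried at full
precision and rounded only at report time, half-up, to 4 decimals (ratios)
and 2 decimals (fold change).

Two classifications follow.  Against the annotation: per library the
observed major arm (strictly larger count) is compared with the
miRBase-designated major arm — the annotated arm for single-arm hairpins,
the MA-ranked arm for two-arm hairpins — and the exchange label collects
the codes of contradicting libraries ("N", "T" or "N;T"); ties contribute
no code.  Between libraries: a tissue switch is called when the two
libraries have different, non-tied major arms.

## Addition-fragment table

Trimmed 3' fragments are tallied weighted by read count (not by unique
sequence); each fragment's percentage is of all addition events, and the
number of distinct fragment kinds is reported separately.  Rows are sorted
by descending percentage with lexicographic tie-breaks.  Fragments longer
than read length − 18 are impossible by construction and asserted against
rather than filtered.

## Categorical Kolmogorov–Smirnov comparison

For one mature in two libraries, the union of observed (start, end) offset
pairs is ordered ascending by start offset then end offset — the natural
5'→3' reading — and numbered 1..K.  This fixed categorical order makes
the two relative-abundance vectors comparable as empirical CDFs; D is the
maximum absolute CDF difference.  Reversing the order can change D, which
is inherent to a categorical axis, so the canonical order is fixed and
tested for determinism.

The p-value treats reads as the sample units (the eligibility floor of
1000 reads only makes sense on that reading): with n_e = n_a·n_b/(n_a+n_b),
λ = (√n_e + 0.12 + 0.11/√n_e)·D and p = Q(λ), the Kolmogorov survival
function (evaluated via `scipy.special.kolmogorov`; tests cross-check a
direct evaluation of the alternating series Q(λ) = 2Σ(−1)^{j−1}e^{−2j²λ²}
to 1e-6).  With read counts in the thousands this is anticonservative for
overdispersed count data; the screen therefore requires strictly more than
8 isomiR types and strictly more than 1000 reads in both libraries, and
applies a stringent raw p < 0.001.  No multiplicity correction is applied
by default (a Bonferroni option exists); an exact permutation p-value is a
documented extension point, not implemented.

## Between-library normalization

Libraries of different depth are related by OLS of log10 expression in
library B on library A over matures expressed (count > 0) in both; zero
counts are excluded rather than pseudocounted, and at least 3 shared
matures are required.  The log10 scale is the default because raw-scale
OLS on libraries of 10^7 reads with an order-one intercept is implausible;
`scale="linear"` is available.  The model is applied as
`x → 10^(slope·log10 x + intercept)` with zero mapping to zero, which
preserves expression rank for positive slope.  A post-fit identity check
(refitting after applying the model) is recorded as `post_slope` and
warned about outside [0.9, 1.1].  Normalization is reported separately
from the arm-ratio analysis, which consumes raw counts by design.

## Synthetic data: what it emulates and what it does not

The simulator plants a mature on both arms of random hairpins and draws
two collapsed libraries from a joint (arm × offset × fragment) multinomial
per hairpin, so every read's origin is known.  Defaults are the study
conditions:

| parameter | default | rationale |
|---|---|---|
| n_hairpins | 20 | enough loci for cohort-level checks at desk scale |
| hairpin length | 70–90 nt | typical human pre-miRNA range |
| mature length | 21–22 nt | keeps every offset combination inside the 18–25 nt read envelope (a 23 nt mature with end offset +3 would exceed it) |
| arm ratio | 2.0 | a moderate, realistic 5p dominance |
| isomiR offsets | 12 types, (0,0) at 0.35, 3'-variation-heavy | mirrors the empirical pattern that 5' ends are more constrained than 3' ends; >8 types keeps loci KS-eligible |
| addition rate | 14% | the published normal-library addition rate |
| addition fragments | published normal-library shares (A 50.93%, U 30.72%, …) with three fillers (UUU, GA, UG) absorbing the unlisted 6.52% remainder | |
| library depth | 100,000 reads each | multinomial noise small enough for tight recovery at desk scale |
| unannotated arm fraction | 0.25 | exercises opposite-arm detection without dominating the reference |

Two constructions make recovery exact rather than merely probable.  First,
hairpins are resampled until no 18-mer occurs twice anywhere in the
reference, so any ≥18 nt read maps to a unique locus.  Second, each
mature's 3' junction zone — its last five nucleotides and the six
positions past its end, covering every junction an end offset in [−5, +5]
can create — is a fixed spacer base C, and addition fragments are
validated not to start with C.  Every appended fragment therefore
mismatches the template at the junction and trim rescue recovers it with
its identity intact, leaving the planted fragment distribution unbiased.
The alternative (mutating drawn fragments to mismatch) would distort the
very distribution being planted.

This is also the honest limitation list: real references contain repeated
k-mers and paralogs (multi-mapping), real additions can coincidentally
extend the template (invisible to any exact-match pipeline, and a known
ambiguity between 3' addition and terminal modification), real mature
tails are not homopolymeric, and no sequencing-error or quality model is
included.  Passing recovery tests therefore demonstrates correctness of
the bookkeeping and statistics under identifiable conditions, not
robustness to those real-data effects.

## Problem sizes and tolerances used in validation

- Mapper/brute-force equivalence: 50 hairpins × 500 reads, every trim length.
- Fold-change recovery: planted 4.0 (ratios 2.0 vs 0.5), 20,000 reads per
  hairpin per library; acceptance band [3.0, 5.3], a 3σ multinomial
  envelope at that depth.
- Addition percentages: ≈85,000 addition events (610,000-read library at
  the 14% rate), per-fragment tolerance 0.6 percentage points (3σ for the
  largest share is ≈0.5 points at that size).
- KS screen: 60 loci at 5,000 reads per side, 10 with 15 percentage points
  of mass moved between types; all 10 must be detected at p < 0.001 with at
  most 2 of 50 null loci flagged.
- Normalization: 2,000 matures, log-linear truth y = 1.3x − 0.15 with
  σ = 0.2 noise; slope and intercept recovered within ±0.05 (≈4σ and ≈3σ).
- KS p-values: agreement with the direct series oracle to 1e-6.
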