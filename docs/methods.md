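# Methods

This note documents the models, conventions, and design decisions
behind `ribofold-te`: what each stage computes, which choices were
genuinely open and how they were resolved, what the synthetic generator
does and does not emulate, and the package's known limitations.

## Coordinate frame and input validation

A transcript is the concatenation 5'UTR + CDS + 3'UTR in 0-based,
half-open transcript coordinates; the three region lengths must sum to
the sequence length and the CDS must be a multiple of 3 when non-empty.
Sequences are canonicalized to the DNA alphabet (U → T) on read; `N` is
allowed and excluded from all frequency denominators. Validation is
per-record for invariant violations (the offending transcript is
dropped and logged) and per-file for structural problems (an id present
in only one of a FASTA/region-table pair is a hard error). `NA`
(case-insensitive) is the only missing-value token in reactivity
tracks; in memory missing values are `nan`. Transcripts missing a
reactivity track in one condition keep their other features and carry
missing values for that condition (logged); imputation happens inside
each train/test split, never globally.

## Translation efficiency

RPKM = count × 10⁹ / (length × library total). TE = log2(RPKM_ribo /
RPKM_rna), defined only when both RPKMs are positive. Decisions:

* **Strict expression filter.** "RNA-seq RPKM over 1" is read literally:
  transcripts are retained iff RPKM_rna > threshold (default 1.0).
* **Zero ribosome counts** exclude the transcript rather than assigning
  −∞ TE, which would poison downstream features.
* **Length denominator** defaults to the full transcript length; a
  `cds` mode is provided (`--length-mode`) since annotation pipelines
  differ on this point.
* **Class definition.** With N filtered transcripts, exactly
  ⌊qN⌋ (default q = 0.25) highest-TE transcripts are labeled *high* and
  ⌊qN⌋ lowest *low*; ties at the quantile boundary are broken by
  lexicographic transcript id so labeling is deterministic. Intermediate
  transcripts are removed from modeling.

## Sequence features (111 by default)

Families and scopes: nucleotide frequency (4 scopes × 4 bases = 16), GC
content (4), in-frame codon frequency (64), amino-acid frequency with
stop as the 21st symbol (21), codon and amino-acid repetitive rates
(2), and the four lengths. The repetitive rate is defined as the
fraction of adjacent identical pairs, (# i : s_i = s_{i+1}) / (L − 1) —
the simplest definition consistent with the name; it is isolated behind
one function so an alternative (e.g. longest-run based) can be swapped
without touching the registry. Codon/amino-acid features are CDS-only
by construction. The registry is an explicit, extensible census: the
default configuration documents exactly which 111 features it produces
and makes no claim beyond that; additional families can be registered
without disturbing feature order, which is deterministic.

## Structural features (132 by default)

**Meta-gene binning.** Each region of length L is split into B = 20
contiguous bins, bin k covering nucleotide indices
[⌊kL/B⌋, ⌊(k+1)L/B⌋). This floor rule is deterministic and
partition-exact: every nucleotide falls in exactly one bin, and for a
gap-free track the length-weighted mean of a region's bin values equals
the region's plain mean to machine precision (this conservation is
asserted in the tests). A bin with no nucleotides (region shorter than
20 nt) or only missing values is missing; by default such transcripts
are kept and imputed downstream rather than excluded, since region
length is itself informative.

**CDS head.** Mean non-missing reactivity over the first six codons
(18 nt) of the CDS, one feature per condition; missing when the CDS is
shorter than 18 nt.

**In silico folding.** The built-in folder maximizes base pairs over
nested (pseudoknot-free) structures with Watson–Crick and G·U pairs and
hairpin loops of ≥ 3 unpaired nucleotides, scoring −1 per pair. Pair
maximization rather than a nearest-neighbor energy model keeps the
folder dependency-free and exhaustively verifiable — the test suite
checks it against a brute-force enumeration of *all* structures for
sequences up to length 14. The dynamic-programming kernel is plain
nested loops, jit-compiled with numba when available (identical results
either way; the pure-Python path is just slower). Energies from an
external thermodynamic folder (kcal/mol) can be imported per scope and
then replace the built-in values. Scopes: whole transcript, each
region, and the CDS head, each raw and per-nucleotide — 10 features.
Note that MFE(whole) ≤ MFE(sub-scope) does *not* hold in general (the
whole-sequence optimum need not contain a sub-interval's optimum), so
no such invariant is asserted.

## Classification protocol

100 stratified random 70/30 splits (|train| = round(0.7 n)); split i is
drawn with seed base_seed + i, so the whole pipeline is byte-identical
given a base seed. Stratification is used for both the splits and the
ten CV folds — the sources are silent on this, and stratification
protects the small classes at no cost. Within each split an exhaustive
grid search maximizes mean cross-validated AUC (ties keep the earlier
grid point), the winner is refit on the full training partition, and
test AUC is recorded. A single-point grid skips the search. Default
grids — forest: trees {100, 500} × max features {√p, p/3} × min leaf
{1, 5}; elastic net: mixing {0.1, 0.5, 0.9} × 10 log-spaced inverse
penalty strengths (10⁻³…10²) — are configurable; no grid is canonical.

Missing values are imputed with training-partition medians inside each
split; features are z-scored (training statistics) for the elastic net
only. The forest's impurity-based importances are normalized to sum to
1 per split, summed within the four feature groups, and averaged across
splits per meta-gene bin. AUC is the rank-based probability that a
random positive outranks a random negative with ties counting ½
(cross-checked against direct pair counting). Models are compared with
a *paired* two-sided t-test on per-split AUC differences, since both
models see identical splits; degenerate cases (zero-variance
differences) are reported as p = 0 with a warning, or NaN when the
vectors are identical.

## Per-bin differential reactivity

The observation unit is the per-transcript bin mean (one value per
transcript per bin), not pooled per-nucleotide reactivities: each point
of a meta-gene curve aggregates transcripts, and the matching test
compares those per-transcript values between TE groups. The two-sample
KS test uses the exact two-sided p-value when |x|·|y| ≤ 10,000 and the
asymptotic Kolmogorov approximation above that. Adjustment is
Benjamini–Hochberg, applied within each condition across its 60 bins
(the family is a single condition's profile; the two conditions are
separate families). Reported significance is −log10(adjusted p). The
delta profile is the per-bin difference of group means, in vivo minus
in vitro; it is missing wherever either side is.

## Synthetic data generator

The generator produces the *structure* of a probing + profiling study,
not its biology:

* **Transcripts**: region lengths uniform in (40–80, 90–180, 60–120) nt
  — short enough that whole-transcript folding is cheap, long enough
  that every 20-bin region is gap-free; CDS starts ATG, ends with a
  stop, i.i.d. nucleotides between (premature stops are not excluded —
  nothing downstream translates beyond frequency counting).
* **Counts**: rna ~ NB(mean 500, dispersion 0.1; Var = μ + φμ²),
  ribo ~ NB(μ·2^te, φ) with te = ±2 per the planted class; library
  totals are column sums × 50 (real libraries contain many more
  features than any analyzed subset). The planted ±2 effect makes
  realized-TE class recovery ≈ 98%, so quantile labeling and planted
  labels nearly coincide.
* **Reactivities**: baseline Beta(2, 5) per nucleotide (right-skewed,
  essentially bounded in [0, 1] like normalized probing reactivities),
  independent across conditions; additive planted effects, clipped at
  0; missing mask i.i.d. at rate 0.05.

Planted effects by scenario (applied to high-TE transcripts only):

* `mesc_like`: in vivo 3'UTR +δ (default 0.15) with a front-loaded
  Gaussian positional profile peaking ~12% into the 3'UTR (≈ bin 42),
  emulating unfolding immediately after the stop codon; in vitro 3'UTR
  −0.05 uniform. The vitro counter-shift is set to a third of the vivo
  peak so the in vivo rearrangement is the dominant signal, matching
  the condition the scenario emulates (in vivo feature importance
  exceeding in vitro).
* `zebrafish_like`: +0.15 uniform on the 3'UTR in *both* conditions
  (so delta ≈ 0 there) plus +0.05 on the in vivo 5'UTR and proximal 30%
  of the CDS.
* `null`: te_effect = 0 and no reactivity effects; classes are noise
  quantiles.

Additive (rather than multiplicative) effects were chosen because the
expected bin means are then analytic (baseline mean 2/7 plus the
planted shift), which makes the recovery tests verifiable by hand. An
optional class-coupled GC shift exists for giving sequence features
planted signal; it is off by default.

What the generator does **not** emulate: sequence-dependent structure
(reactivity is independent of the underlying sequence, so the in silico
MFE group is uninformative by construction and its near-zero importance
is expected, not a finding); ribosome-profiling periodicity and coverage
bias; correlated missingness; between-replicate variability; any
coupling of TE to sequence composition beyond the optional GC switch.
Passing recovery tests therefore demonstrates that the pipeline detects
effects of the planted kind and location at the planted magnitude — not
that real mESC or zebrafish data would yield the same numbers.

## Problem sizes and numerics

The recovery runs use n = 400 transcripts, 20 splits, and a reduced
forest grid (100 trees, √p features, leaf {1, 5}); the null control
uses n = 300 with a single-point grid for the AUC check and 20
generator replicates at n = 400 for the false-positive rate. These
sizes give stable estimates (binomial noise on a 20-split mean AUC is
~0.01) while keeping a full run in minutes on one CPU. Random-number
streams: every stage derives its seed from one base seed (scenario
seeds offset by small constants, split i at base + i); all seeds are
kept below 2³¹.

Tolerances: frequency-family sums and importance sums are checked to
1e-6…1e-9; bin-mean conservation to 1e-9 (observed ~1e-16); KS oracle
agreement to 1e-9 on p and 1e-12 on D. Ties: TE quantile ties break
lexicographically; CV grid ties break by grid order; AUC ties count ½.

## Limitations

* The built-in folder is a pair-maximization model, not a free-energy
  model; its energies are in "pairs", not kcal/mol, and should be
  replaced by imported energies for any thermodynamic interpretation.
* The feature registry is a documented census, not a claim to reproduce
  any particular published feature set; compositions beyond the default
  families (codon-adaptation indices, uORFs, Kozak context) are out of
  scope.
* Raw-read processing (alignment, reactivity derivation) is out of
  scope; the pipeline starts from counts and per-nucleotide tracks.
* Per-bin KS tests treat bins independently; no spatial smoothing or
  cluster-level correction is applied.
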