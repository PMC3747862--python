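# Methods

## Scoring model

A binding-site model is a pair-aware position-specific scoring matrix built
from a gapless-interior alignment of `n` sites over `l` columns. Column
probabilities `f_i(u)` are estimated from the non-gap letters of column `i`
plus an additive pseudocount (default 0.25 per letter); pair probabilities
`f_{i,j}(u,v)` for `1 ≤ j − i ≤ K` come from rows that are non-gap at both
positions (pseudocount 0.0625 per pair). The background `f(u)` defaults to
the pooled non-gap letter counts of the aligned sites, and the pair
background is the independence product `f(u)·f(v)`, so pair scores measure
dependence relative to independence. All logs are base 2; scores are in
bits. The *scope* `K` bounds the distance between scored pairs; `K = 0` is
the classical additive PSSM.

Two scoring variants exist. Genomic windows are gap-free and use the plain
sum. During alignment and when scoring an isolated candidate site of
arbitrary length, the sequence is padded with `l − 1` gap letters per end so
that every relative placement against the matrix is a scorable window; gap
letters then contribute the precomputed column (or pair-table) minimum.
This convention also resolves an ambiguity in the sliding-score definition,
which references the plain matrix although its augmented windows contain
gaps. The best window is the sliding score; ties break to the leftmost
window, and the forward strand wins exact cross-strand ties (determinism
matters for testing; the choice is otherwise arbitrary).

## Progressive alignment

Binding sites of one factor share a short conserved core with irrelevant
flanks, and shorter database entries tend to carry fewer irrelevant bases.
The aligner therefore seeds with a shortest site (first in input order among
ties) and repeatedly: builds the gap-aware PSSM of the current partial
alignment (full rebuild each round — `n` is small and a rebuild is simpler
than incremental updates), picks the next shortest unaligned site (profile
score breaks length ties, input order breaks score ties), places it over
both strands, and merges it, growing the alignment on overhang. Input sites
must be gap-free and at least 4 bases long; the scope must be smaller than
the shortest site. Every input site appears in the output exactly once,
recoverable by stripping gaps and undoing the recorded strand.

End-trimming removes columns from each end up to the first column whose
coverage `C_i` (fraction of non-gap letters) and information content
`IC_i = max(0, 2 + Σ_u f_i(u) log2 f_i(u) − ê(n_i))` strictly exceed the
thresholds; `ê(n) = 3/(2 ln2 · n)` is the asymptotic small-sample correction
for four letters (exact small-`n` tables would be an extension; the
asymptotic form is standard and monotone). `IC` uses pseudocount 0 and is
clamped to `[0, 2]`. The default configuration `C_min = 0.4, IC_min = 0` is
applied between alignment and PSSM construction, not inside the aligner.
Trimming is idempotent; rows whose letters are entirely trimmed away stay in
the alignment as all-gap rows and simply stop contributing.

## ChIP-seq variant

Peak sequences bury the core in hundreds of flanking bases and the shortest
peak may miss the core entirely, so four things change. (1) Every peak is
clipped to 100 bp centred on its point-source offset, clamped at the peak
bounds (most true sites lie within 50 bp of the called peak). (2) Once the
partial alignment holds more than two sequences it is trimmed before each
PSSM rebuild with *adaptive* thresholds — the means of `C_i` and `IC_i`
over current columns (skipped when no column strictly exceeds both means,
e.g. perfectly uniform coverage) — then capped by repeatedly dropping the
lower-IC end column until at most 15 columns remain and both ends carry
positive IC. (3) When more than five equally short candidates compete for
the next slot, a seeded sample of five competes. (4) The finished alignment
is refined: trim, rebuild the PSSM, re-place *every* clipped peak (the
spec's ambiguity between re-placing all peaks or only aligned ones is
resolved to all), and repeat until the trimmed profile's summed IC is
unchanged (|Δ| < 1e-9, floating-point sums) for three consecutive
iterations. The trim/re-place map can enter a limit cycle this rule never
terminates — a period-3 IC cycle has been observed — so a 50-iteration cap
returns the best alignment seen (highest trimmed IC), flagged unconverged.

Because a shortest peak may be a poor seed, the whole procedure runs from
six seeds (the shortest clipped sequence plus five sampled ones) for every
scope in 0..8, on a seeded sample of at most 300 peaks; the candidate with
the highest summed IC after trimming wins. One motif occurrence per peak
sequence is assumed throughout.

## Scanning and empirical p-values

Scanning scores every window on both strands and keeps the higher score.
The default prediction cutoff is the minimal sliding score of the sites the
matrix was built from, so every constituting site is recovered by
construction. Pair terms make window scores sums of dependent variables,
ruling out the exact convolution p-value available for `K = 0`; p-values
are therefore empirical for every scope uniformly: an i.i.d. sequence long
enough for 40000 windows is simulated from the model's stored background
(the letter composition of its training sites), all windows are scored
both-strand, and the upper 5% tail is retained. Scores below the 95th
percentile report the sentinel `"0.05+"`; above it, `p` is the fraction of
null windows scoring at least as high, giving a resolution of
1/40000 = 2.5×10⁻⁵, with 0 meaning smaller than that. The 40000-window
default is chosen to match that printed resolution and is configurable.

## Evaluation protocol

Alignment quality is measured by the search performance of the resulting
PSSM under seeded ν-fold cross-validation (ν = 10). Per fold: training
sites are aligned (alignment scope set equal to the search scope, as the two
are closely related), trimmed at `C_min = 0.4, IC_min = 0`, and turned into
a PSSM. Each held-out site is planted at a uniform random position (the
placement policy is unstated upstream; uniform is the neutral choice) in a
fresh 2000-base sequence simulated from a first-order Markov chain. Every
window of the site's length is scored by its best augmented placement
against the PSSM, both strands. Windows overlapping the planted site by
more than half its length are hits; the rest are non-sites. The site's
score is the best hit score and its rank is one plus the number of non-site
windows scoring at least as high; pooled normalized ranks give the ROC
curve and AUC (the step-curve area equals `mean(1 − (rank−1)/m)` exactly).
Fold assignment and all backgrounds derive from the seed alone, so scope
grid searches (`K_s` in 0..min(10, l_min−1), smaller scope preferred on
ties) compare identical folds.

One caveat is worth stating plainly: the best-hit statistic maximises over
~`l_s` correlated hit windows while each non-site contributes one window,
so under a pure null it is biased to an AUC of roughly `h/(h+1)` (~0.85
empirically), not 0.5. Between-method comparisons cancel the bias; absolute
null calibration does not. `cv_evaluate` therefore also offers
`statistic="planted_window"`, which scores only the exactly planted window
— exchangeable with non-sites under the null — and is the right measurement
for negative controls. For search methods predicting variable-length sites,
recall/precision and `F_β` (β = 0.5, weighting precision) are provided with
the embedding-aware hit rule for short predictions.

## Synthetic data

The generators are pure functions of their seed and emulate what curated
databases and ChIP-seq pipelines deliver, with recorded ground truth
(core interval and strand per sequence) sufficient to score alignment
recovery and AUC without external data.

- `make_pwm(length, ic_per_column, seed)`: each column mixes a random
  dominant letter with the uniform distribution, the weight solved by
  bisection so the realised IC hits the target to machine accuracy.
- `sample_site_set`: cores drawn from the PWM, i.i.d. uniform flanks with
  per-side lengths uniform over a range, optional whole-site reverse
  complementation. Defaults mirror the study conditions used throughout the
  tests: 8-bp core at 1.5 bits/column, 30 sites, flanks 0–6 per side, 20%
  reverse-complemented.
- `sample_paired_site_set`: cores with adjacent-pair dependence but uniform
  marginals — each letter follows a fixed random permutation of its
  predecessor with probability 0.95 (10-bp core, flanks 0–2 by default), so
  scope-0 models see almost no signal while pair terms capture it. The
  defaults are set so the dependence is strong enough that scope selection
  is reproducible across seeds rather than a coin flip.
- `sample_peak_set`: 100–400-bp peaks, one core planted with its midpoint
  within ±30 bases of the recorded point source (within the ~50-bp
  accuracy reported for peak callers), either strand. For ChIP recovery
  studies the planted core is a fixed 8-mer (2 bits/column), matching the
  notion of recovering a consensus word.
- `promoter_like_chain()`: a fixed, mildly GC-skewed first-order transition
  table with a depleted CpG step — a synthetic stand-in for mammalian
  promoter composition, not trained on genomic data.
- `shuffle_sites`: per-site letter permutation, the motif-destroying
  negative control. Controls are paired with a background chain trained on
  the shuffled sites themselves: promoter-derived backgrounds are
  composition-matched to promoter-resident sites, and without matching,
  letter composition alone separates sites from background.

What passing on these fixtures does *not* show: real TFBS sets have
correlated curation artefacts, non-uniform flank composition, cores with
internal dependence structure richer than first-order, and peaks with
multiple or missing motif occurrences — none of which the generators
emulate. Results on synthetic data bound what the implementation computes,
not how the method behaves on any particular genome.

## Problem sizes and numerical choices

The test suite and the acceptance script run: 50 site sets (30 sites each)
for alignment recovery; 10 sets plus 10 shuffled controls for
cross-validated discrimination; 2 pair-dependent sets for the scope grid;
one 300-peak set for the ChIP pipeline; 1000 random instances for the
brute-force scoring comparison; 40000 null windows for p-value calibration.
These sizes give pooled statistics tight enough for the assertions (e.g.
~300 pooled ranks put the null AUC's standard error near 0.02) while a full
run stays in the minutes range on one core.

Degenerate inputs and ties are handled deterministically: leftmost window
and forward strand on score ties, input order on residual site ties,
alphabetical order on consensus ties, smaller scope on equal grid AUCs.
Zero probabilities raise an error directing the caller to a pseudocount
rather than silently flooring logs. IUPAC ambiguity codes are rejected by
the readers (the model assigns them no score); an explicit flag drops such
records instead. All coordinates are 0-based half-open everywhere.

## Known limitations

Gapless-interior alignment cannot represent two-block motifs with
variable-length spacers; such factors align at the most prevalent spacer
length. The ChIP variant discovers a single motif per data set under the
one-per-sequence assumption. Empirical p-values are lower-bounded by the
simulated window count, and the refinement loop, while usually convergent,
is only guaranteed to terminate by its iteration cap.
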