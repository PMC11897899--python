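# Methods

## Scope and data model

`clonodiff` operates on clonotype tables, not raw reads: each input row is
a rearrangement clonotype — a (V gene, J gene, CDR3 amino-acid sequence)
triple with a read count — for one sample at one locus (TRB or IGH).
Upstream V(D)J annotation is assumed done. Clonotypes are keyed at the
amino-acid level by default, matching the amino-acid-level CDR3 analyses
downstream; rows sharing a key merge by summing counts, and a nucleotide-
level key is available (`key_nt=True`) for sensitivity analysis, since
published pipelines differ on this point. Counts are authoritative: input
frequency columns are ignored for computation and recomputed as
count / total reads (a warning notes disagreement). CDR3 strings are taken
exactly as given — whether the conserved C104/F-W118 anchors are included
is an upstream convention the package does not second-guess.

Gene names are normalized (allele suffix `*NN` stripped, locus prefix
upper-cased, ambiguous `A/B` calls resolved to the first gene with an
`ambiguous` flag retained). A gene call whose locus prefix contradicts the
declared locus raises an error rather than being silently re-locused:
mislabelled segments in source tables are a real failure mode and should
surface, not disappear.

## Comparison weightings

Spectratypes, composition matrices, usage vectors and pairing matrices all
support two weightings: `clonotypes` (each unique clonotype counts once;
the default) and `reads` (each clonotype contributes its read frequency).
The clonotype default reflects that these analyses characterize the
*breadth* of the repertoire; the reads switch exposes clone-size-weighted
variants since logo and usage conventions vary across tools. Diversity
indices are the exception: they are always computed on read-weighted
frequencies, because evenness and dominance are meaningless without clone
sizes.

Group-level pairing matrices are unweighted means of per-sample matrices,
so each patient carries equal weight regardless of sequencing depth; a
pooled mode renormalizes the summed matrix instead. Per-sample pairing
marginals reproduce the usage vectors exactly (same weighting) — this is
asserted, not assumed.

## Statistical tests

* **Mann–Whitney U** (per-length, per-gene, Shannon-norm and inverse-
  Simpson comparisons): two-sided. Exact when min(n₁, n₂) ≤ 8 — via the
  classical count recursion when the pooled values are tie-free, or by
  full enumeration over the observed mid-ranks when ties are present and
  C(m+n, m) ≤ 10⁵ — otherwise a normal approximation with mid-ranks,
  tie-corrected variance and 0.5 continuity correction. At the package's
  motivating scale (15 samples per group, fraction-valued data with
  frequent ties) the approximate path is always taken; the threshold is
  fixed so results are reproducible bit-for-bit.
* **Welch t** (clonotype count, d50 index, mean CDR3 length): unequal-
  variance statistic with Satterthwaite df. Zero pooled variance returns
  p = 1 with a `zero_variance` flag instead of raising, so batch reports
  over many metrics never abort on a degenerate one.
* **Fisher exact** (2×2 arm-wise outcome comparisons): two-sided p as the
  sum of hypergeometric point probabilities ≤ that of the observed table,
  with 10⁻⁷ relative slack guarding floating-point equality of symmetric
  tables. The odds ratio is the sample estimate ad/bc (∞ when only bc = 0,
  NaN for 0/0).
* **Benjamini–Hochberg** step-up q-values accompany every p-value family
  (per-length, per-gene within segment). Raw p-values remain the primary
  report — single-study repertoire analyses conventionally report them —
  and the report marks which calls survive q < 0.05.

The exact-test implementations are validated in the test suite against
independent brute-force oracles (subset enumeration over mid-ranks;
log-factorial hypergeometric summation) and against scipy's
implementations, which are deliberately not used as the computation path.

## Diversity indices

For clone frequencies p₁…pₙ (read-weighted, summing to 1):

* d50 count k = min{k : Σᵢ≤k p₍ᵢ₎ ≥ 0.5} over descending frequencies;
  d50 index = 100·k/n (the percent-of-clonotypes convention; the raw count
  is reported too since both variants circulate).
* Shannon H = −Σ pᵢ ln pᵢ (nats); normalized Shannon (Pielou evenness)
  H/ln n, defined as 0 for n = 1.
* Inverse Simpson 1/Σ pᵢ².

Identities used as tests: a uniform repertoire attains evenness 1, inverse
Simpson n and d50 count ⌈n/2⌉; a monoclonal one attains 0 / 1 / 1; the
Rényi ordering inverse-Simpson ≤ exp(H) ≤ n holds on every sample. Merging
two clones can only decrease H and inverse Simpson; note this is *not*
true of normalized Shannon, whose ln n denominator also shrinks — the
normalized index can rise under a merge, which is one reason d50, evenness
and inverse Simpson need not co-vary in sign between groups. The report
therefore prints every index's direction explicitly. No rarefaction is
applied by default; depth normalization, where wanted, belongs upstream.

Landmark survival rates are patient-count proportions (k of N event-free
at the horizon), not Kaplan–Meier estimates; the KM estimate at the
horizon is reported alongside. A patient censored before the horizon
counts as not event-free under the count convention (the conservative
reading; the count of such patients is reported, and
`censored_event_free=True` flips the convention). Kaplan–Meier curves and
the log-rank test come from lifelines. Adverse-event tables are
patient-denominated: one count per patient per term at the patient's
maximum grade for that term.

## The synthetic study generator

The generator emulates the statistical structure the analysis assumes —
it defines the conditions under which the pipeline is validated, and its
parameters are not adjusted per run.

Per sample: V and J usage drawn from Dirichlet(prior × c) with
concentration c = 250 controlling sample-to-sample usage noise; CDR3
lengths from a discretized Gaussian (mean 15 aa for TRB, 20 aa for IGH,
sd 1.2, truncated to 8–28), placing the modal windows at 14–16 and
19–21 aa respectively; CDR3 strings with fixed anchors (N-terminal C;
C-terminal F for TRB, a 70/30 W/F mix for IGH) and interior residues
i.i.d. from a stated 20-letter multinomial enriched for small/flexible and
charged residues — positional structure beyond the anchors is deliberately
not modelled, since observed logo structure concentrates at the anchors;
clone-size weights follow a Zipf law (exponent 1.5, per-sample N(1.5, 0.1)
jitter providing realistic inter-sample spread in diversity), converted to
counts by a single multinomial draw of 30 000 reads over 1 000 candidate
clonotypes (zero-count clonotypes drop out, leaving ~500–700 observed —
a deliberate scale-down from deep-sequencing clonotype counts that
preserves the frequency structure the statistics operate on).

Planted effects define recoverable ground truth: per-gene usage
multipliers applied to the target group's probabilities before
renormalization, and a clonal expansion multiplying the top-10 clone
weights in the target group (lowering evenness and inverse Simpson there).
The default TRB study plants 3× shifts on TRBV29-1, TRBV4-1 and TRBJ1-3
plus a 3× expansion in the responder group; the default IGH study plants
3× shifts on six IGHV genes (IGHV1-45, IGHV3-20, IGHV3-48, IGHV3-49,
IGHV4-4, IGHV5-51) and no expansion, so IGH group diversity is comparable
by construction.

Two calibration choices matter and were fixed by power analysis, not by
iteration against test outcomes:

* the planted genes sit on a *low-frequency* baseline (prior weight 0.6
  vs 1.0 background, ~1% usage): a 3× shift is then strongly detectable at
  15-vs-15 scale while the shifted gene stays several noise-SD below the
  usage leaders, so the generator can reproduce both target findings at
  once — named differential genes *and* unchanged most-connected genes
  (TRBV20-1/TRBV12-3, TRBJ2-7/TRBJ2-1, IGHV3-21) in both groups;
* c = 250 puts the group-mean separation of a 3× plant at z ≈ 5.8
  (recovery power ≈ 1 at the 0.05 level) while keeping per-sample usage
  realistically variable.

Because the two usage leaders are deliberately close (as they are in real
repertoires), their *mutual* order within the top-2 is within sampling
noise; recovery contracts are therefore stated on the top-2 set.

Determinism: each sample's RNG stream derives from
`SeedSequence([seed, sample_index])`, so outputs are byte-identical for a
given (config, seed) and independent of generation order.

The cohort generator allocates best responses per arm (default: exact
allocation to 0/43/20/6 CR/PR/SD/PD among 69 TP patients and 0/11/4/4
among 19 FP patients, shuffled; a multinomial mode draws from the implied
proportions). Survival uses a competing-risks construction: OS is
exponential at the group median (28.27 months for responders, 22.33
otherwise), time-to-progression is exponential with rate
ln2/medPFS − ln2/medOS, and PFS = min(TTP, OS) — both marginals are then
exactly exponential at the configured medians (18.37 / 8.07 months for
PFS) and PFS ≤ OS holds by definition. Censoring thins each endpoint
independently: with probability `censor_rate` the observation is cut at a
uniform fraction of its time (default 0 — fully observed). Adverse events
are per-term Bernoulli draws at configured patient-level probabilities
with a fixed conditional grade distribution (0.45/0.35/0.15/0.04/0.01 for
grades 1–5), putting the expected grade-≥3 rollup near 12.5%.

### What the generator does and does not establish

Passing recovery tests shows the pipeline detects effects of the planted
kind at the planted size under Dirichlet-multinomial noise; it does not
certify performance on real repertoires, which add sequencing error, V/J
mis-assignment, clonal lineage structure (especially for IGH somatic
hypermutation), covariate-driven usage differences and depth
heterogeneity — none of which are modelled. Null-calibration tests (raw
p < 0.05 rate ≈ 0.05 without plants) validate the testing machinery, not
any claim about biological null distributions.

## Problem sizes

Defaults throughout were chosen once as realistic scale-downs: 15 samples
per group (the motivating study design), 1 000 candidate clonotypes and
30 000 reads per sample, 200 replicates for Monte-Carlo recovery/null
rates, 40 seeds for modal-window rates, and 20 000 patients for
large-sample survival-median checks. `scripts/acceptance.py` recomputes
all headline quantities at these sizes in a few minutes on one CPU.

## Known limitations

* D-gene usage, CDR3 clustering/network analyses, repertoire overlap
  indices, richness estimators (Chao1/ACE) and Cox regression are out of
  scope.
* The d50 percent convention (100·k/n) is sensitive to the observed
  clonotype count n; comparisons across depths should use the optional
  downsampling in upstream processing or interpret the raw d50 count.
* The exact Fisher two-sided convention ("sum of tables no more probable
  than observed") is one of several in circulation; mid-p and doubled
  one-sided variants will differ in borderline tables.
* The AIRR TSV reader accepts the standard column names plus overrides;
  it does not implement the full AIRR schema (no validation of nucleotide
  junction consistency, no repertoire metadata blocks).
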