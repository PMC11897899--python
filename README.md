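# clonodiff

Group comparison of immune-repertoire (TCR-β / IGH) clonotype tables, for
studies that ask whether treatment responders and non-responders differ in
their adaptive immune receptor repertoires — plus the two-arm clinical
cohort statistics such studies report alongside.

`clonodiff` consumes AIRR Rearrangement-style clonotype tables (one row per
clonotype: V/J call, CDR3 amino-acid sequence, read count) for two patient
groups and computes:

* **CDR3 spectratypes** — the distribution of CDR3 lengths per sample,
  compared per length with the Mann–Whitney U test and by per-sample mean
  length with Welch's t-test;
* **positional amino-acid composition matrices** (the numeric substrate of
  a sequence logo) for the modal length window;
* **clonal diversity** per sample: d50 (smallest number of top clones whose
  cumulative frequency reaches 50%, also as a percentage of clonotypes,
  100·k/n), Pielou-normalized Shannon entropy H/ln n, and inverse Simpson
  1/Σpᵢ²; compared between groups with the t-test (clonotype count, d50
  index) and Mann–Whitney U (Shannon norm, inverse Simpson);
* **differential V/J gene usage** — per-gene Mann–Whitney U on per-sample
  usage fractions over the union gene universe, with raw p and
  Benjamini–Hochberg q;
* **V–J pairing matrices** whose row/column marginals reproduce the V and J
  usage vectors exactly, with top-linked gene rankings;
* **cohort statistics** — RECIST response classification (ORR = CR+PR,
  DCR = CR+PR+SD), per-arm Fisher exact tests, landmark survival rates,
  Kaplan–Meier curves with the log-rank test, and patient-denominated
  adverse-event tables.

Because real repertoire sequencing data are rarely redistributable, the
package includes a fully seeded **synthetic study generator**: two groups
of 15 TRB and 15 IGH repertoires with configurable CDR3 length models
(modal windows 14–16 aa for TRB, 19–21 aa for IGH), Zipf-distributed clone
sizes, Dirichlet sample-to-sample usage noise, and *planted* group effects
(per-gene usage multipliers and clonal expansions) recorded in a
ground-truth manifest, so every pipeline stage can be validated by
parameter recovery.

## Statistical conventions

* Mann–Whitney U: exact p (null-distribution recursion, or mid-rank
  enumeration under ties) when min(n₁, n₂) ≤ 8; otherwise a tie-corrected
  normal approximation with continuity correction. Two-sided throughout.
* Fisher exact (2×2): two-sided p as the total hypergeometric probability
  of tables no more likely than the observed one (the convention used by
  mainstream statistics software).
* Welch t with Satterthwaite df; zero-variance inputs return p = 1 with a
  flag rather than aborting batch reports.
* Benjamini–Hochberg step-up q-values are reported alongside every family
  of raw p-values.

## Worked example

Simulate a study (deterministic under `--seed`), analyze the TRB
repertoires, and summarize the clinical cohort:

```sh
clonodiff simulate --out demo --seed 42
clonodiff analyze --repertoire demo/trb_repertoires.tsv \
    --design demo/trb_design.tsv --locus TRB --out demo/trb_analysis
clonodiff cohort --cohort demo/cohort.tsv --out demo/cohort_stats
```

which prints

```
wrote simulated study to demo (seed 42)
  TRB: 15 samples/group, 3 planted usage shifts, expansion=yes
  IGH: 15 samples/group, 6 planted usage shifts, expansion=no
TRB: modal window [14, 15, 16], differential V at raw p<0.05: ['TRBV29-1', 'TRBV4-1', 'TRBV11-2', 'TRBV5-1']
cohort: n=88, ORR 61.4%, Fisher p=0.793
```

and `demo/trb_analysis/report.md` contains (excerpt):

```
## Diversity
- d50_index (welch): mean non_ORR 0.334281, mean ORR 0.420334, p = 0.000503
- shannon_norm (mann_whitney): mean non_ORR 0.456387, mean ORR 0.363781, p = 4.143e-06
- inverse_simpson (mann_whitney): mean non_ORR 5.89013, mean ORR 4.0793, p = 6.837e-05

## Differential V/J usage
- V genes at raw p < 0.05: TRBV29-1, TRBV4-1, TRBV11-2, TRBV5-1 (surviving BH q < 0.05: TRBV29-1, TRBV4-1)
- J genes at raw p < 0.05: TRBJ1-3, TRBJ2-5, TRBJ2-4, TRBJ2-6 (surviving BH q < 0.05: TRBJ1-3)
```

Reading the numbers: the default generator plants a 3× usage shift on
TRBV29-1, TRBV4-1 and TRBJ1-3 in the responder (ORR) group plus a clonal
expansion there. The analysis recovers exactly those genes as the BH-
surviving differential calls (two additional genes clear the raw 0.05
threshold, as expected by chance across ~60 tests), and the expansion shows
up as lower evenness — lower normalized Shannon and inverse Simpson — with
a higher d50 *index* in the expanded group (the expansion also shrinks the
observed clonotype count n, and 100·k/n rises faster than k falls). The
cohort command reproduces the response-table arithmetic: ORR 61.4% with a
between-arm Fisher p of 0.793.

Library use mirrors the CLI:

```python
from clonodiff import (default_trb_config, simulate_study,
                       analyze_study, diversity_profile)

samples, design, manifest = simulate_study(default_trb_config(), seed=42)
result = analyze_study(samples, design)
result.significant_genes("V")       # differential V genes, sorted by p
diversity_profile(samples[0])       # d50 / Shannon-norm / inverse Simpson
```

## Layout

```
src/clonodiff/
  io.py         AIRR-style TSV reading/writing, gene-name normalization
  stats.py      Mann-Whitney, Welch t, Fisher exact, Benjamini-Hochberg
  cdr3.py       spectratypes, length comparisons, composition matrices
  diversity.py  d50 / normalized Shannon / inverse Simpson + comparisons
  usage.py      V/J usage, differential testing, V-J pairing
  cohort.py     response, landmark, Kaplan-Meier/log-rank, adverse events
  simulate.py   seeded two-group repertoire and cohort generator
  report.py     end-to-end analysis bundle and writers
  cli.py        `clonodiff` simulate / analyze / cohort / report
docs/methods.md  model and design notes
```
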