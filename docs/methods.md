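# Methods

## The problem and the model

A range-finding experiment is a cheap, unreplicated pilot that samples a
wide dose × recovery-time grid once per cell to locate where in the
design space a biological process of interest responds — the "sweet
spot" — before committing to a replicated study.  Because there is no
replication, nothing here is a per-gene hypothesis test: the protocol is
a screen built from fold-change thresholds, a competitive gene-set
statistic, and correlation magnitudes.

The pipeline runs, in order:

1. **Subject-effect correction** (multi-subject designs only).  Per
   gene, an intercept + subject-offset model with offsets constrained to
   sum to zero is fitted by ordinary least squares over the ok samples;
   returned values are observed minus fitted offset, re-centred so the
   per-gene grand mean is preserved.  With single-replicate cells there
   is no information to estimate variance components, so this
   fixed-effect point correction is used rather than a mixed model; in
   the balanced case the two coincide.  Dose and time are deliberately
   not included as fixed effects: with one sample per (subject,
   condition) they would be confounded with the residual.  The known
   consequence is leakage — a subject that only sees one dose has its
   offset partially absorb that dose's true effect, spreading an echo of
   the signal into the subject's other samples.  The leakage is visible
   in the in-vivo synthetic preset as extra enriched cells at active
   doses outside the planted time window; the lowest-p cell remains a
   planted cell.
2. **Ratio grids.**  Every design cell is reduced to a per-gene log2
   fold change against a declared baseline: the global t = 0 control
   (per subject where subjects exist; with several qualifying baseline
   samples their per-gene mean — geometric mean on the raw scale — is
   used), the dose-0 sample at the same time (so fold changes reflect
   dose response, not time drift), or untreated-vs-t0 (dose-0 cells over
   time, the input of the drift filter).  Cells lacking a baseline are
   omitted with a warning, not an error.
3. **Background (drift) filter.**  A gene is removed when its
   |log2 FC| exceeds the cutoff (default 1, i.e. two-fold) in *any*
   untreated cell: growth, circadian and other baseline processes change
   expression without exposure, and any later change of such a gene
   cannot be attributed to dose.
4. **Design-space restriction.**  A cell is a DEG-counting exercise:
   genes with |log2 FC| strictly greater than the cutoff.  Cells with a
   count at or above the threshold (default 2,000, ≈10% of a 24,302-gene
   mouse array; a threshold < 1 is read as a fraction of the gene total)
   are flagged as transcriptome-wide stress responses and excluded.
   Boundary conventions: strictly-greater for DEG calls,
   greater-or-equal for the restriction; both configurable.  The
   restriction is computed on the vs-t0 DEG map over all genes, before
   the drift filter is applied.
5. **Competitive enrichment.**  Per usable cell and per gene set, a
   one-sided test of whether set genes carry larger statistics than the
   rest.  `alternative="mixed"` (default) ranks |log2 FC| — change in
   either direction counts; `up`/`down` use signed values.  The default
   `rank` method is a Wilcoxon mean-rank test with midranks on ties:
   when the number of equal-size subsets is small (≤ `max_exact`,
   default 20,000) the p-value is the exact fraction of subsets whose
   mean rank reaches the observed one; otherwise a normal approximation
   with finite-population and tie correction
   (Var = k·σ²ranks·(n−k)/(n−1)) is used.  The `permutation` method
   draws seeded random same-size gene subsets and applies the add-one
   estimator p = (1 + hits)/(1 + B), which can never return zero.  Both
   variants assume set genes are, on average, no more correlated than
   random genes; violations make p-values optimistic, which is accepted
   for a screen whose output is a *location*, not a significance claim.
6. **BH and the adaptive color key.**  Benjamini–Hochberg is applied
   across the cells of each set's diagram (the diagram is the visual and
   decision unit; a `bh_family="global"` option spans sets × cells
   jointly).  With pmin the diagram's lowest adjusted p: if pmin ≤ 0.3
   the color scale runs linearly from pmin (red) to pmin + pmax (grey);
   otherwise a fallback scale from 0.3 to 0.5 is drawn and no sweet
   spots are declared — the red anchor is unoccupied, and the fallback
   exists to display non-findings.  "Red" is operationalized as the
   lowest `red_band_fraction` (default 0.25, boundary inclusive) of the
   active scale, since the original definition is visual.  pmax presets:
   0.2 for sparse in-vitro-like signal (the conservative default for new
   data) and 0.01 for dense in-vivo-like signal.
7. **Dose-response screen.**  Per set gene and recovery time, Pearson r
   between the dose values (natural scale, no log) and the log2 FCs,
   with dose 0 participating as an anchor at ratio 0 (the ratio is
   defined against dose 0 itself; excludable by flag).  Times with fewer
   than `min_points` (default 4) doses are left absent; constant ratio
   vectors give no r.  |r| strictly above 0.8 is "relevant"; genes never
   relevant are dropped from the display table; time columns containing
   a sweet spot at any dose are starred.  Row order — earliest relevant
   time, then descending |r| — is presentation only.

## Tunable parameters

| parameter | default | units / meaning |
|---|---|---|
| `deg_cutoff`, `background_cutoff` | 1.0 | log2 FC; two-fold change |
| `restriction_threshold` | 2000 | DEG count (fraction of genes if < 1) |
| `pmax` | 0.2 (preset 0.01 in-vivo) | adjusted-p span of the color scale |
| `red_band_fraction` | 0.25 | share of the active scale called red |
| `fallback_floor` / `ceiling` | 0.3 / 0.5 | fallback color scale anchors |
| `correlation_threshold` | 0.8 | |r| relevance mark |
| `min_points` | 4 | doses needed for a correlation |
| `n_permutations` | 9999 | permutation-method draws |
| `max_exact` | 20000 | subset budget for exact rank p |

Gene sets shrinking below 20 genes after intersection with the filtered
data are flagged unstable: the removal of single genes by filtering can
flip their result.

## The synthetic generator

The generator's two presets emulate the murine UV case-study layouts:
`invitro_like` — 6 UV-C doses {0, 0.25, 0.75, 2.25, 6.7, 20} J/m² ×
8 recovery times (10 min–48 h), one sample per cell plus a single t = 0
control (49 columns); `invivo_like` — 6 UV-B doses {0, 90, 180, 360,
450, 720} J/m² × 7 times (1–48 h), two subjects per dose sampled
alternately, each with a per-subject pre-exposure baseline at (0, 0)
(54 columns; additive per-subject offsets, SD 0.3 log2 units).

Per gene, baseline expression is N(8, 2) on the log2 scale and noise is
i.i.d. N(0, σ) with σ = 0.25 by default — a typical single-array
technical spread for normalized two-color data; expression here is
already log-ratio-scale array intensity, so no count model is
appropriate.  On top of that: planted modules (amplitude × dose-shape at
their active cells; shapes `linear`, `saturating` d/(d+K) with K the
median active dose, `threshold`, all normalized to 1 at the strongest
active dose), drift genes (amplitude × time-shape in *all* samples,
dose 0 included; shapes `step`, `linear` ramp, `sine`), and
global-stress cells where 15% of the transcriptome moves by ±2 log2
units.  Preset drift counts (1,854 in-vitro / 1,814 in-vivo at the full
24,302-gene array size, scaled proportionally for smaller grids) and the
stress-cell placement (late times and the highest in-vitro dose) mirror
the case studies' reported background and non-specific zones.  Module
genes, drift genes are disjoint by construction; the truth record
(module genes and cells, drift genes, stress genes per cell, subject
offsets) suffices to compute every downstream expectation at σ = 0
without re-simulation.

What the generator does *not* emulate: probe-level artifacts, dye bias,
amplification chemistry, inter-gene correlation within modules beyond
the shared mean shift, heavy-tailed noise, and missing-at-random cells
other than the explicit failure mask.  Passing tests therefore show the
statistics and bookkeeping are right under the stated model, not that
real arrays behave this way — in particular, real gene sets are
correlated and real p-values will be optimistic.

## Numerical choices

- Midranks on ties; exact rank p-values compare half-integer rank sums,
  which are exact in binary floating point, so exact-mode results are
  reproducible to the bit.
- DEG boundary: strictly greater than the cutoff (a gene at exactly
  two-fold is not a DEG); restriction boundary: count ≥ threshold.
- Red-band boundary inclusive (color = red_band_fraction is sweet).
- A constant statistic vector yields p = 1 with a warning (no ordering
  information).
- Expression TSVs are parsed with round-trip float precision, so a
  write/read cycle is bit-exact and two runs with the same seed produce
  byte-identical artifacts.
- BH is the standard step-up procedure; note it is not idempotent
  (re-adjusting adjusted values changes them), so adjusted values are
  computed exactly once per diagram.
- Failed samples carry NaN and are excluded from every computation;
  baselines are never failed by the failure mask because every ratio
  needs them.

## Test problem sizes

The suite checks exact oracle equality on all-subset enumeration
(≤ 10 genes, set ≤ 4), null calibration on 2,000 simulated cells
(300 genes, 30-gene sets), planted recovery on 100 seeded 5 × 6-grid
runs (2,000 genes, 30-gene module, amplitude 1.5 vs σ = 0.5), zero-noise
filter exactness at the full 24,302-gene array size, and pipeline
determinism on the in-vivo preset at 3,000 genes — sizes chosen so the
whole suite runs in well under a minute of compute per check while
keeping every statistical property at the scale where it is informative.

## Known limitations

- Subject-offset leakage in unreplicated multi-subject designs (above).
- The competitive test's exchangeability assumption is knowingly
  violated by real co-regulated sets; p-values are screening scores.
- Single-cell (non-dose-monotone) activations are found by enrichment
  but largely invisible to the correlation screen — by design, the two
  views answer different questions.
- No correlation p-values are computed; |r| > 0.8 on ≤ 7 points is a
  magnitude mark, not inference.
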