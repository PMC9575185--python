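# Methods

This note documents the models, parameter choices and numerical
conventions behind `dtpescape`, and what the synthetic-data validation
does and does not establish about real data.

## Single-cell copy-number profiling (`sccnv`)

**Windows.** Reads are counted in windows of width 5 Mb placed every
2.5 Mb per chromosome (starts 0, 2.5 Mb, …; the last partial window is
dropped). A read is assigned to every window containing its **midpoint**:
with 50% overlap an interior read is counted twice, once per overlapping
window, and the midpoint rule avoids the read-length edge bias that
any-overlap assignment would introduce. Coordinates are 0-based
half-open; a midpoint exactly on a window start belongs to that window.

**Aberrant-window exclusion.** Windows whose total count across cells
falls strictly below the `low_quantile` (default 0.05) or strictly above
the `high_quantile` (default 0.99) of window totals are masked. Linear
interpolation between order statistics defines the quantiles (this
affects which windows sit at the bound). Strict inequalities mean values
exactly at the bound are retained — with mostly tied totals the
alternative (masking ties) degenerates to masking everything. This step
targets shared coverage artefacts: centromere-like pileups and
unmappable regions.

**Normalization.** Three ordered steps on retained windows:

1. `v = log2(count + 1)` (pseudocount 1 keeps zero counts defined);
2. per window, subtract the median of `v` across cells — the profile now
   reads as log₂ fold change in copy number relative to the population
   average, and the across-cell median of every window is exactly zero;
3. per cell, the unique increasing affine map sending that cell's
   (10th, 90th) percentile values onto the reference anchors, where the
   reference is the mean of per-cell anchor values. This two-anchor
   percentile ("enrichment") normalization absorbs depth and
   distribution differences between cells; with the mean-anchor
   reference it is idempotent, and after it every cell's anchor
   percentiles agree to float precision.

Cells with zero total count are dropped with a warning. The anchor
choice embeds an assumption: **aberrant windows must be a small minority
(≲10%) of a cell's windows**, otherwise the 90th percentile lands inside
the aberration and the affine map compresses the signal. On a real
(~3,200 Mb) genome a 15-Mb event is ~0.5% of windows and the assumption
is comfortable; synthetic fixtures must use genomes large enough to
respect it (the standard fixture uses 4 × 100 Mb, putting one 15-Mb
event at ~4.5% of windows).

**Event calling.** Windows with value ≥ `amp_log2` (or ≤ `del_log2`) are
marked; consecutive marked windows merge into runs, masked windows
strictly inside a run bridge it, and a run is emitted when its genomic
span (first window start to last window end) strictly exceeds
`min_span` (default 10 Mb). The *definition* of a large event — at least
a two-copy change on a near-diploid background — corresponds to
|log₂| ≥ 1 (log₂(4/2) = 1), and that is the default threshold. For
*detecting* planted two-copy events under noise, the recovery benchmark
marks windows at half the expected amplitude (|log₂| ≥ 0.5): a detector
thresholded exactly at the expected signal level has 50% per-window
power by symmetry, so the midpoint between baseline (0) and signal (1)
is the standard decision boundary. The threshold is exposed because the
appropriate cutoff depends on the baseline ploidy of the cell line.

**Contingency.** Cells are cross-tabulated by group membership and
whether they carry ≥1 event (each cell counted once), giving the 2×2
table consumed by the exact test.

## Synthetic single-cell coverage (`gen_sc_coverage`)

Per cell, read positions are drawn segment-wise with intensity
proportional to local copy number (baseline ploidy plus planted CNV
deltas for carrier cells). Overdispersion enters as a per-cell gamma
size factor with shape 1/d and scale d (mean 1, variance d), making
marginal window counts negative binomial with dispersion d (default
0.2). Placing the dispersion at the cell level models what dominates
shallow single-cell libraries — library-size variability — and is
precisely the component the per-cell percentile normalization is
designed to remove; window-level overdispersion of the same magnitude
would correspond to log₂ noise of ~0.65 SD per window, under which no
fixed threshold can recover ±1-amplitude events.

Two optional realism fields make the exclusion filter meaningful:
a shared log-normal per-2.5-Mb-tile capture efficiency (default off;
the standard fixture uses SD 0.15) emulating mappability/GC bias, and
explicit aberrant regions (multiplier 5 for repeat-pileup-like, 0.05
for unmappable-like) shared by all cells. Without them, a clean
simulated genome's only total-coverage outliers are the CNV windows
themselves (seven shared carriers raise regional totals by ~8%), and
the 99th-percentile filter would mask the signal it exists to protect.
Reads are fixed-length (75 nt) single-end intervals; base content,
conversion chemistry and mapping are not simulated.

**Standard recovery fixture** (also used by the acceptance script):
85 cells (42 positive, of which 7 carry one +2-copy 15-Mb amplification;
43 flat negative), 4 × 100 Mb diploid genome, 60,000 reads per cell,
dispersion 0.2, efficiency SD 0.15, one high and one low aberrant region
per chromosome, 20 seeds. Depth is set so that even cells in the lower
tail of the size-factor distribution keep their normalized event
amplitude above the 0.5 detection boundary; the few cells with extreme
low factors (gamma factor ≲ 0.25, roughly 2–3% of cells) remain hard to
call — these correspond to the very-low-coverage libraries that
single-cell workflows remove at QC, a step intentionally not applied
here so the sensitivity figure reflects all carriers. Reported metrics
aggregate over seeds: mean sensitivity, mean false events per flat cell,
median contingency p.

## 3′-end quantification (`threeprime`)

**Windows.** For each high-confidence transcript, walk back 500 nt from
the annotated 3′ end through its exons (spliced coordinates), emitting
one genomic interval per traversed exon; shorter transcripts contribute
their full exonic extent. Whether the original analysis used spliced or
purely genomic walk-back is not documented anywhere we could rely on;
the spliced version is chosen because it preserves the "500 transcript
nucleotides" semantics across introns.

**Filtering and counting.** Exonic filtering requires full containment
of the read in the merged exon union (the strictest reading of
discarding reads outside annotated exons; any-overlap is available).
Reads are assigned to gene-level windows (interval union over the
gene's transcripts) by midpoint, on the strand **opposite** the
transcript for dUTP-style directional libraries (`same` and `both` are
selectable, and `opposite + same = both` exactly). A read over windows
of several genes counts once per gene (logged).

**Normalization.** `bulk` mode scales samples to equal totals and takes
log₂(x+1) — appropriate for intact libraries. `three_prime` mode takes
log₂(x+1) and applies the shared two-anchor percentile normalization at
(50, 90): degraded libraries concentrate their reads into the 3′
windows, producing a global distribution offset against intact
libraries that the percentile match removes. It cannot remove
gene-specific residual bias (e.g. transcript-length interaction with
partial degradation); the benchmark quantifies what remains.

**Degradation generator.** Fragments survive with probability ∝
e^(−λ_deg·d), d the 3′ distance; sampling weight per transcript is
abundance × (1 − e^(−λ_deg·L))/λ_deg (abundance × L at rate 0, the
uniform-coverage limit). Reads crossing a splice junction are shifted
into the exon holding their 3′ end so every simulated read is a single
genomic interval; at 75 nt against ≥600-nt exons this distortion is
negligible and keeps BED6/SAM round-trips exact.

## Behaviour clustering (`clusters`)

Selection requires significance (p < cutoff) in ≥1 contrast **and**
fold change strictly >4 in ≥1 contrast; the two conditions may be met in
different contrasts. Both 0.01 and 0.05 are defensible cutoffs for the
upstream differential calls (sources differ); the default is 0.01 and
the parameter is explicit. Clustering: per-gene profiles over condition
means are z-scored, clustered with correlation distance and average
linkage, and cut at k = 3; these specific choices are ours (only
"hierarchical clustering" is inherited) and they recover planted
archetypes at the benchmark noise level. Cluster labels map to
behaviours by one-to-one assignment maximizing correlation between
cluster means and the three signature vectors (down-everywhere;
down-in-G1-only; up). Degenerate inputs (identical genes) log a warning
and collapse to one effective cluster.

The cluster-(i) split: recovery = (EdU⁺ − drug-G1)/(untreated − drug-G1),
clipped at 0; genes with recovery ≥ `recovery_fraction` (default 0.5)
are `S-induced`, the rest `persistently-low`. Non-recovery in
G2/M-sorted cells is already what defines cluster (i), so it is not
re-tested in the split; with `recovery_fraction = 0` every cluster-(i)
gene is S-induced by construction. The 0.5 default is a judgement call
(the original distinction was functional-annotation-driven); it is the
midpoint between no and full recovery.

## Escape simulator (`escape`)

States: arrested-G1, S, G2/M, labelled-arrested, resistant lineages,
dead. Escape and death of arrested cells are exponential with rates
λ·κ and δ per day (κ the CDK4/6i factor); S and G2/M are fixed
durations (defaults 8 h and 4 h — conventional values, not measured for
this line under drug; they are parameters). The mechanism itself is
qualitative in origin; the state space, exponential waiting times and
per-S-phase resistance probability are this package's modelling
choices. Resistance is a single binary hit with probability `p_resist`
per completed S phase; the resistant cell founds a lineage at its
division time that doubles synchronously every `resistant_doubling`
hours, reaching a colony at ⌈log₂ 50⌉ = 6 doublings (size 2ᵏ). Death
applies to arrested cells (rate δ) and at division
(`p_death_on_cycle`); resistant cells neither die nor respond to κ
(low-dose CDK4/6 inhibition does not impair resistant proliferation).
Labelling: a cell is EdU-labelled iff its S interval overlaps the label
window; labelled cells complete S and then arrest permanently before
division (`edu_arrests`, default on). The simulation is an exact
event-driven queue (aggregate Gillespie draws for the arrested pool,
scheduled completions for stage transitions), bit-reproducible per
seed. Default n0 = 10,000 is a desk-scale stand-in for a 2.5 × 10⁵-cell
culture; rates per cell are scale-free, so only absolute colony-count
statistics depend on n0.

Labelling laws used for calibration: continuous labelling follows
F(t) = 1 − e^(−λκt) (with zero death), so λ = ln2/11 d⁻¹ gives F(11 d)
= ½. A pulse of length p labels the cells in S during the window; the
first-order renewal prediction λ(p + t_S) acquires a second-order
occupancy correction because cells already in S/G2M cannot escape:
x(1 − x) with x = λ(p + t_S). At the ~5% labelling level this ~5%
relative correction is visible at Monte-Carlo precision and is used
when calibrating λ to a target pulse fraction.

## Survival and contingency statistics (`stats`)

* **Fisher exact**: two-sided by probability ordering — sum the
  hypergeometric probabilities of all tables with the observed margins
  whose probability does not exceed the observed one (a relative
  tolerance of 1e−7 in log space guards float noise among
  equal-probability tables). This is the convention of the major
  statistical packages; other two-sided rules exist and give different
  values. Verified against exact integer enumeration for every table
  with N ≤ 30.
* **Log-rank (Mantel–Cox)**: Σ(O−E) over distinct event times with
  hypergeometric variance; tied events handled simultaneously; p from
  χ²(1).
* **Cox proportional hazards**: Newton–Raphson on the partial
  likelihood with Efron tie correction by default (weekly-resolution
  resistance times are heavily tied; Breslow selectable — they agree to
  1e−10 without ties). Covariates are centred for numerical stability;
  convergence requires max |score| < 1e−8 within 50 iterations, with
  step-halving; diverging coefficients (|β| > 20) flag suspected
  complete separation instead of reporting silent garbage. Wald CIs and
  p-values; `risk_reduction = 1 − HR`. The score test at β = 0 is
  reported and agrees asymptotically with the log-rank test for a
  single binary covariate.
* **Kruskal–Wallis**: rank-based H with the standard tie correction; p
  from χ²(k−1); identical-value degenerate input returns H = 0 with a
  warning.

Week-resolution times are treated as exact event times with censoring
at study end.

## What the synthetic validation shows — and does not

The generators reproduce the statistical structure the methods assume:
copy-number-proportional coverage with NB dispersion and shared window
artefacts; exponential 3′ survival in degraded libraries; archetypal
expression behaviours; exponential or mechanistic time-to-event
cohorts. Passing the recovery benchmarks demonstrates that the pipeline
is internally correct and recovers planted truth under realistic noise
— it does not demonstrate robustness to everything real data adds:
GC-dependent amplification interacting with copy number, segmental
aneuploidy of real cancer genomes, isoform complexity and overlapping
genes, UMI-less PCR duplicates, or model misspecification of the escape
process (e.g. non-exponential dormancy exit). Where those matter the
exposed parameters (thresholds, anchors, dispersions, stage durations)
are the knobs a user should revisit.

## Problem sizes

Default validation sizes were chosen to keep the full test suite and
the acceptance run at desk scale: 20 seeds × 85 cells × 60k reads for
CNV recovery, 100k reads per RNA library, cohorts of 500 cultures per
group × 10 fits, Monte-Carlo populations of 2 × 10⁴ cells. All are
parameters of the corresponding benchmark functions.
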