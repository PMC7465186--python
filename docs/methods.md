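# Methods

`liquidmix` implements a multi-analyte liquid-biopsy analysis for
castration-resistant prostate cancer (CRPC): three independent blood-based
assays are analyzed separately and then integrated per patient. This note
documents the models, the rules, the tunable parameters, and the design
choices made where the procedure was genuinely open.

## 1. In situ CTC calling

Each analyzed cell carries a rolling-circle-product (RCP) count per marker
transcript (KLK3, AR-V7, AR-FL). Healthy-control material shows a small
background of false-positive signals (≈0.7–0.8% of PBMCs with one AR-V7 RCP,
up to two AR-FL RCPs per cell), so per-marker cut-offs are derived from the
controls as

    cutoff(marker) = max RCP count observed in any control cell + 1,

with cut-off 1 for a marker never observed in controls. Applied to the six
healthy-control samples shipped as reference occupancy tables, this yields
the operational thresholds ≥1 KLK3, ≥2 AR-V7, ≥3 AR-FL RCPs/cell. The
`max+1` form is the unique monotone rule that reproduces all three
thresholds from those control distributions; it guarantees by construction
that no control cell is ever called a CTC under cut-offs derived from the
same controls.

A cell is a CTC when it reaches the cut-off for at least one marker;
classification is monotone in every count. Patient summaries count CTCs,
per-marker positivity and the maximum RCP count per marker.

**Heterogeneity.** Intrapatient CTC heterogeneity is only described
qualitatively in the assay literature (cells expressing different
transcripts, or the same transcript at very different levels), so it is
operationalized as: ≥2 CTCs and (the positive-marker sets of two CTCs
differ, or some marker positive in ≥2 CTCs spans more than `het_fold`
(default 2) between its minimum and maximum count). The fold threshold is a
config knob.

**Distribution summaries** use the standard {0, 1, 2, 3, >3} RCPs/cell
occupancy layout: percentages at two decimals, fractions-of-patients at
integer precision, both rounded half-up. Quartiles are linear-interpolation
quantiles of raw per-cell counts, with the `>3` bin represented by 4.
CellCollector controls lack total cell counts; they contribute observed
positive cells to cut-off derivation but cannot be summarized as
distributions (totals are required and enforced).

## 2. Whole-blood RT-qPCR (ΔCq)

Target Cq values are normalized to the GUSB reference gene,
ΔCq = Cq(target) − Cq(GUSB), averaged over technical replicates; lower ΔCq
means higher expression. Reactions with no amplification within the 45-cycle
run are imputed at Cq 46 *before* normalization; imputed values participate
in threshold derivation. A sample whose reference gene failed is
unevaluable and reported, never imputed.

The per-gene positivity threshold is the minimum mean ΔCq among healthy
controls; a patient is positive iff its ΔCq is strictly below threshold.
Strict inequality is the only tie rule consistent with controls being
negative by definition, and together with the minimum construction it
guarantees zero positives among the controls that defined the threshold.
Replicates are paired by index and averaged at the ΔCq level (config switch
`average_level="cq"` averages Cq first; with matching replicate structures
and mean-averaging the two differ only when pairings are unbalanced).

## 3. Plasma shallow-WGS copy-number analysis

Input is fragment counts in 50 kb bins over a PAR-masked genome (a SAM/BAM
adapter assigns fragments to bins by start coordinate, half-open
convention). The chain is:

1. **Depth normalization** — ratio = count / mean(count over unmasked
   autosomal bins), so the autosomal mean ratio is exactly 1.
2. **GC correction** — a LOWESS fit of ratio vs GC fraction (span 0.3,
   2 robustness iterations; both exposed) over unmasked autosomal bins is
   divided out. Zero-count bins get a floor log2 of −4 to keep segmentation
   finite. A degenerate GC range skips correction with a warning.
3. **Segmentation** — exact penalized least-squares segmentation per
   chromosome: breakpoints minimize total within-segment squared error plus
   `penalty × var(chromosome bin log2)` per breakpoint (penalty default 10,
   minimum segment 3 bins), solved by an optimal-partitioning dynamic
   program. An exact search is used rather than greedy recursive splitting
   because a short *interior* amplification — the very target of this
   analysis — requires two breakpoints that are individually weak but
   jointly decisive: the best single split of a chromosome containing an
   interior m-bin event at height Δ gains at most m²Δ²(1/(p+m) − 1/n),
   while the two flanking splits jointly gain mΔ²(n−m)/n. The greedy rule
   therefore misses focal events at realistic tumor fractions that the
   exact optimum finds. The test suite checks the implementation against an
   independent brute-force enumeration of all admissible segmentations on
   small instances.
4. **Focal events** — a segment is an event iff all six criteria hold:
   (1) length < 20 Mb; (2) log2 > 0.2 for amplifications / < −0.2 for
   deletions (strict); (3) 1–100 overlapping genes; (4) log2 differs from
   the length-weighted mean of segment material within 20 Mb on both sides
   by ≥ 0.2 if the segment contains a known tumor driver gene, ≥ 0.58
   otherwise, in the event's direction (inclusive ≥; both flanks pooled
   into one weighted mean, truncated at chromosome ends — per-side
   averaging is available behind a config flag); (5) segmental-duplication
   coverage ≤ 50% of the segment; (6) known germline-CNV coverage < 50% of
   the segment (fraction configurable). Deletion contrasts mirror the
   amplification direction. Every criterion's pass/fail is recorded per
   segment. AR-amplification status is positive iff a called amplification
   contains the AR gene.
5. **Naive tumor-fraction surrogate** — for the most aberrant autosomal
   segment spanning ≥ 2 Mb, assuming one clonal single-copy gain/loss:
   tf = 2·|2^L − 1| clipped to [0, 1], quantifiable iff tf ≥ 3%. This is a
   deliberately simple surrogate, labelled "naive surrogate" in every
   output: it ignores ploidy, subclonality and multi-copy states, and is
   not a probabilistic copy-number model.

X-chromosome handling: the `haploid_x` flag recenters chrX segments by
+1 log2 for male genomes so the autosomal thresholds apply on the same
scale; the synthetic genome is simulated diploid everywhere, so the flag
defaults to off in the demo.

## 4. Multi-analyte integration

The ledger is a patients × assays matrix over {positive, negative,
not_assayed}; `not_assayed` is first-class and never coerced to negative.
Denominators deliberately differ: per-assay percentages use assayed
patients only, the overall informative rate uses all enrolled patients with
at least one assayed result (a patient with no assayed entries violates the
ledger contract and is excluded with a report). A patient is *informative*
if any assayed result is positive; *resistant* if AR-V7 (either transcript
assay) or ctDNA AR amplification is positive; *exclusive* if exactly one of
those three assays is positive — exclusive and multi-assay counts partition
the resistant patients. Concordance between the in situ and qPCR call for a
marker is the agreement fraction over co-assayed patients. All percentages
are rounded half-up (two decimals in occupancy tables, integers for patient
fractions).

## 5. Synthetic cohort generator

The generator emulates the statistical structure of each input; defaults
are the study conditions, chosen once:

* **Cells** — background RCP counts per marker are categorical over 0–3
  with probabilities calibrated to the published PBMC control marginals
  (e.g., AR-V7: 99.23% zeros, 0.77% ones); two control samples of 30,000
  cells. Patients (19) mix 2,000 background cells with tumor cells drawn
  per marker from negative binomials loosely matched to the VCaP positive
  control (means 0.01 / 2.4 / 9 for KLK3 / AR-V7 / AR-FL, dispersion 2 —
  the distributional family is a modelling choice; only marginal occupancy
  tables are published). A patient has CTC-like cells with probability
  10/19, then 1–10 tumor cells, matching the reported prevalence and range.
* **Cq tables** — 16 controls + 16 patients, 2 replicates, Cq ~
  Normal(mean, sd) clipped to (0, 45]; gene/group means chosen so targets
  sit 1.5–2 cycles lower in patients; AR-V7 no-amplification probability
  9/16 in both groups as reported, small (5%) dropout elsewhere, none for
  the reference. Dropouts are emitted as *missing* — imputation to 46 is
  the analysis module's job, mirroring the division of labour.
* **Plasma bins** — a miniature genome (chr1–chr3 of 20 Mb, chrX of 15 Mb,
  50 kb bins) so a full run takes seconds; expected count per bin =
  depth × blend/2 × gc_bias(gc), blend = tf·CN + (1−tf)·2 inside the
  amplification locus (default chrX:5.0–5.5 Mb, CN 4, containing the AR
  driver gene) and 2 elsewhere; counts are Poisson. Depth defaults to 180
  fragments per diploid bin (≈11 M reads over a 60k-bin genome). GC bias is
  a smooth unimodal multiplicative quadratic centered at GC 0.45 (amplitude
  0.3) — enough to exercise the LOWESS correction without modelling
  chemistry. The first five chrX bins are emitted masked (PAR surrogate).
* **Tumor fraction** — default 0.25. A CN-4 amplification blended at
  fraction tf has expected log2 = log2(1 + tf), so the 0.2 magnitude
  criterion is only satisfiable for tf > 2^0.2 − 1 ≈ 0.149; 0.25 places the
  expected segment at log2 ≈ 0.32, about 3.5 Poisson standard errors above
  the cut at the default depth, giving a detectable but not trivial spike.
  The spike-recovery study uses 100 replicates at tf 0.25 and 100 flat
  replicates; tumor-fraction recovery uses a 5 Mb CN-3 (single-copy) gain
  at tf ∈ {0.1, 0.2, 0.4}, 5 replicates each, compared as means.
* **Ledger fixture** — exact per-assay (positive, assayed) marginals,
  defaulting to the reported cohort margins; used to test integration
  arithmetic independently of the upstream assays.

Each generator draws from its own RNG stream (base seed + stable offset),
so outputs are byte-reproducible and adding one generator never perturbs
the others.

**What the generator does not emulate:** real chromosome structure and
coordinates, fragment-level data (bins are the unit), joint correlation of
markers within single cells, amplification-efficiency and preamplification
effects in qPCR, mappability variation, subclonal copy-number states, and
any coupling between a patient's assay results. Passing tests therefore
demonstrate correctness of the *rules and estimators* under the assumed
statistical structure, not clinical performance on real cohorts.

## 6. Numerical conventions and degenerate inputs

Half-up rounding throughout (via `decimal`); 0-based half-open intervals
everywhere (bins, BED tracks, segments); ties at a qPCR threshold are
negative; a segment's class is assigned by sign before the magnitude
criterion is tested; flankless segments auto-fail the contrast criterion;
empty inputs (no cells, no controls, all-zero counts, no co-assayed
patients) raise errors rather than returning silent zeros. Segmentation
tie-breaks (exactly equal penalized costs) resolve to the earlier
breakpoint candidate; with continuous noise they do not occur in practice.

## 7. Known limitations

The tumor-fraction surrogate is biased low when segment boundaries dilute
the event and cannot separate tumor fraction from copy number; the
heterogeneity fold-threshold is a heuristic; the focal caller's 0.2/0.58
contrast margins are taken as stated without an inclusive/strict
specification (implemented inclusive, flagged in the parameter docs); and
the known-CNV filter uses segment-coverage rather than reciprocal overlap
(fraction configurable). Survival/response regressions and probabilistic
tumor-fraction modelling are out of scope.
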