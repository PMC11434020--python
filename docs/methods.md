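# Methods

`stempcr` simulates the computational stages of a bisulfite-free,
single-CpG methylation assay pipeline for colorectal-cancer screening:
candidate-site mining from methylation arrays, in-silico
methylation-dependent restriction digestion, foldable-primer (hairpin)
design, and Ct-based clinical statistics. This note records the models,
their assumptions, the defaults that matter, and the places where the
design was genuinely open.

## Synthetic data model

All pipeline inputs are generated, never downloaded.

**Beta matrices.** Per-site methylation fractions are drawn from
`Beta(m*kappa, (1-m)*kappa)`, the standard bounded-support noise model
for array beta values; `kappa` (dispersion, default 30) controls
spread (variance `m(1-m)/(kappa+1)`). A profile plants `n_differential`
sites (case mean vs control mean, defaults 0.5 vs 0.2) among null sites
(default mean 0.15). Coordinates default to a single chromosome at
100 bp spacing; tests that exercise coordinate-aware ranking supply
their own. What this emulates: a two-class tumor/paracancerous design
of roughly 300 vs 300 training samples with a 64 vs 64 held-out set.
What it does not emulate: array normalization artifacts, batch effects,
probe cross-reactivity, or spatially correlated methylation beyond the
planted layout — so passing recovery tests demonstrate the selection
machinery, not robustness to real-array pathology.

**Methylated sequences.** Random sequences at a configurable GC
fraction with CG dinucleotides *exactly* where requested (accidental
CGs from the random background are removed), and symmetric methylation
marks on a subset. This keeps digestion outcomes fully determined by
the configured dyads.

**Stool cohorts.** One row per sample across five diagnosis classes
(normal, CRC, AA, polyp, enteritis; CRC rows carry a uniform stage
I–IV). Each marker amplifies with a per-class detection probability;
detected reactions draw Ct ~ Normal(30, 2) cycles, nondetects carry a
sentinel Ct of 45.0 (the 40-cycle program ceiling plus margin) so ROC
analysis on Ct is always well defined. ACTB Ct ~ Normal(20, 1.5)
truncated at the QC cutoff, with a configured fraction (default
36/465 ≈ 7.7%) pushed above it. Default class sizes (161/205/31/18/14)
and detection probabilities mirror the cohort sizes and per-class
positivity rates of the two headline stool markers (e.g. SDC2-6:
91.2% in CRC, 4.3% in normals, 58.1% in AA). The generator does not
model bacterial background DNA, inhibitor carryover, or Ct correlation
between markers beyond shared detection events.

All generators take a single integer seed; identical seeds give
bit-identical outputs.

## Site mining

1. **Prefilter:** per-site two-sided pooled-variance t-test; keep
   p < 0.05. Zero-variance sites report p = 1 rather than erroring.
2. **Importance:** the Chen–Lin F-score
   `F = [(m+ - m)^2 + (m- - m)^2] / (s+^2 + s-^2)` with sample
   variances; defined as +inf when only the numerator survives a
   degenerate denominator.
3. **Coordinate-aware ranking:** `adjusted = F * (1 + 0.1 * k)`, where
   `k` counts other surviving sites within 1000 bp on the same
   chromosome — co-methylation concentrates within about a kilobase, so
   clustered discriminative sites are promoted. The multiplicative form
   and the 0.1 bonus are this package's choice (no canonical form
   exists); a zero bonus recovers pure F ranking. Ties break by
   adjusted score, then chromosome, then position — fully
   deterministic.
4. **Wrapper selection:** walk the ranked list; candidate joins the
   panel only if mean cross-validated accuracy rises by more than
   `epsilon = 0.005` (absolute); changes within epsilon mark it
   redundant, larger drops mark it noise. CV is 10 repeats of an 80%
   class-stratified subsample split into 5 stratified folds, all
   seeded. The classifier is a linear SVM (C = 1) with per-fold
   standardization: the least-assumption choice that keeps decision
   scores monotone for AUC. If nothing enters and the best single site
   is at chance, that site is returned with a warning flag.
5. **Evaluation:** refit on the full training set, report held-out
   accuracy at the decision boundary and decision-score AUC; both
   resubstitution and test-set figures are returned because published
   "accuracy" can mean either.

A consequence of improvement-only acceptance worth knowing: when
planted effects are strong enough that one or two sites already
classify near-perfectly, additional true sites are (correctly) labeled
redundant — the panel saturates at the accuracy ceiling rather than
growing to the full planted set.

## Restriction digestion

Enzymes are declared in a JSON registry as an IUPAC motif with the
position of the methylcytosine, a strand rule, and a cut rule. GlaI is
`R[mC]GY`, palindromic (both strands of a symmetrically methylated dyad
must satisfy the motif), cutting between the methylated C and the G to
leave blunt ends. MspJI (`[mC]NNR`) and FspEI (`C[mC]`) recognize on
either strand; their distant cut offsets are configurable but default
to recognition-only, since cut placement outside GlaI does not affect
coverage or assayability logic here. Digestion is all-or-none: no
kinetics, no partial digestion, no hemimethylation (marks are symmetric
by construction — a known simplification).

A methylated CpG is **assayable** when it is cleavable and the template
immediately 3' of the cut — 40 bases by default, the shortest span that
plausibly fits the capture and target-specific primer footprints —
contains no further cleavable site. Non-assayable sites may be replaced
by the nearest assayable CpG within 100 bp (inclusive at exactly
100 bp; ties toward the lower coordinate), reflecting co-methylation of
close neighbors.

**Coverage** of an enzyme is the probability that a symmetrically
methylated dyad is cleavable. For iid flank models it is computed by
exact enumeration over all flank combinations within the motif's reach
(a few thousand terms) and cross-checked by seeded Monte Carlo. Under
uniform base composition: GlaI 25% (purine 5' x pyrimidine 3' =
0.5 * 0.5), MspJI 75% (either-strand purine at +3: 1 - 0.5^2), FspEI
43.75% (1 - 0.75^2). A printed figure of ~50% for FspEI is consistent
with GC-rich CpG-context composition rather than uniform flanks, which
is why composition is a parameter here, not a constant.

## Hairpin design and thermodynamics

`build_tfp` assembles AP + FR + CRc with CRc the reverse complement of
the template's first bases (3' end flush on the cut terminus). FR is
user-supplied or generated (seeded, GC-biased) under a
cross-complementarity filter: candidates pairing more than 4 contiguous
bases with AP or CRc are rejected, since such stretches nucleate stems
outside the intended fold.

The linear-phase product P2 is modeled directly as its net molecular
outcome: the TFP, then the reverse complement of the template segment
3' of the capture footprint (the future loop, where the probe and TSP
bind), then FRc at the 3' tail. A single primer-extension step cannot
produce this molecule from the capture geometry alone — it is the
multi-round product in which the copy-back stalls at the modified FR/AP
junction — and the package models the outcome rather than the rounds.
P3 is the FR:FRc fold; P4 appends the reverse complement of AP by
self-priming, giving a hairpin whose 3' end is structurally flush (zero
overhang, checked, not assumed).

Stem stability uses the unified SantaLucia nearest-neighbor DNA/DNA
parameters (Biopython's `DNA_NN3` table): dH/dS summed over stem steps
plus initiation and terminal corrections, the 0.368·N·ln[Na+] entropy
salt correction at 50 mm monovalent salt, and a hairpin-loop penalty
from the standard loop-length dG37 table (treated as purely entropic,
interpolated between tabulated sizes, Jacobson–Stockmayer-style
extrapolation beyond 30). The hairpin is unimolecular, so
Tm = dH/dS with no concentration term. Acceptance is strict:
Tm > 66.0 °C **and** dG(66 °C) < 0; equality at the threshold fails.
Methoxy-modified FR bases are counted and reported but treated as
thermodynamically neutral — their effect on amplification efficiency is
an empirical observation, not a nearest-neighbor rule. Stem predictions
for assays of this type are usually made with commercial web tools
whose salt and concentration settings are not published; this parameter
set is fixed and open instead, and the regression fixtures in the tests
pin its values.

`amplicon_predict` delimits the exponential-phase product by AP and the
TSP footprint on P4, verifies the probe sits strictly between the FR
and TSP footprints, and reports sub-spans that tile the amplicon — on
the sequenced (reverse-complement) strand the order reads
TSP … probe … FR … AP. The two annealing temperatures reported are
bimolecular nearest-neighbor Tms of the capture region and the TSP, a
deliberate simplification.

## Diagnostics

* **QC:** exclude samples with ACTB Ct strictly above 24.5 (the
  boundary itself is retained); missing reference values are excluded
  with their own reason.
* **Relative level:** `2^-(Ct_marker - Ct_ACTB)`; the sentinel maps to
  the corresponding floor value. (How the original tissue analysis
  quantified "relative methylation level" is unstated; this delta-Ct
  convention is a declared choice.)
* **Group tests:** Lilliefors-variant KS normality screen at alpha
  0.05 on both groups (the plain KS test with estimated parameters is
  anticonservative, hence the Lilliefors correction); t-test if both
  pass, else two-sided Mann–Whitney with tie correction. Constant
  groups go to Mann–Whitney.
* **ROC:** scores are -Ct (earlier amplification = more positive);
  sentinel nondetects sit at the negative extreme. AUC by trapezoid
  over all unique thresholds, 95% CI by Hanley–McNeil. Youden cutoff by
  exhaustive scan; ties break toward higher sensitivity (screening
  context: prefer missing fewer cases at equal J).
* **Proportions:** Clopper–Pearson exact intervals; undefined rates
  (zero denominators) are reported as not-applicable, never as 0.
* **Stepwise panel:** forward entry by Rao score test (p < 0.05),
  removal by exact likelihood-ratio refit (p > 0.10) — an exact-LR
  stand-in for the conditional-likelihood approximation some packages
  use, with the just-entered marker exempt from immediate removal to
  guarantee termination. Perfect separation falls back to a small
  ridge-stabilized fit (lambda = 1e-3, intercept unpenalized) and is
  flagged. Nondetects enter as the sentinel value rather than being
  dropped, preserving "no amplification = negative" semantics.
* **Marker combination:** the OR rule over binary calls; its
  sensitivity dominates every member and its specificity is dominated
  by every member, which the tests check on every generated dataset.
* **Correlation / clustering:** Spearman on Ct (robust to the sentinel
  ties; the original figure's method is unstated, rank correlation is
  the safer choice), with constant markers flagged and zeroed; Ward
  linkage on z-scored markers with deterministic leaf ordering.

## Problem sizes and verification

The test suite regenerates everything from seeds: digestion
conservation on 1000 random sequences; AUC and F-score oracle
equivalences on 1000 random instances each at 1e-12; the stepwise
logistic model against an independent scipy-based maximum-likelihood
replay on 100 seeded problems; mining recovery on 10 seeds of a
205-site / 200-sample matrix plus 10 study-shaped runs (299/298 train,
64/64 test); diagnostic calibration on 100 seeded cohorts of 240
samples with exact-binomial bands. Enzyme coverage closed forms are
exact enumerations cross-checked by 1e5-dyad Monte Carlo within three
standard errors (`scripts/acceptance.py` recomputes these).

## Known limitations

* Symmetric methylation only; hemimethylated dyads are not
  representable, so GlaI's duplex requirement is never partially met.
* Thermodynamic values are internally consistent but not calibrated
  against any commercial predictor's (unpublished) settings.
* The stool generator draws marker detections independently given
  class, understating between-marker correlation seen in real cohorts;
  OR-rule gains on synthetic data are therefore optimistic.
* Clinical endpoint values reported for assays of this kind
  (sensitivities near 95%, AUCs 0.9–0.95) depend on patient cohorts
  that are not publicly deposited and are outside what synthetic
  calibration can or should reproduce.
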