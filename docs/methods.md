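# Methods

`gliopanel` interprets the outputs of a combined DNA/RNA targeted sequencing
panel for CNS tumors as a single assay: gene-level copy-number estimates,
small-variant calls, and fusion transcripts are turned into the molecular
calls that drive modern glioma classification, without recourse to FISH or
IHC. This note describes the models and rules, their assumptions, the
tunable parameters, what the synthetic-cohort generator does and does not
emulate, and the numerical choices made where the design was open.

## 1p/19q co-deletion from pooled gene copy numbers

Whole-arm co-deletion of 1p and 19q (the hallmark of oligodendroglioma) is
detected from the arithmetic mean of the linear copy-number estimates of all
panel genes on those two arms: six genes on 1p (MTOR, MYCL, MPL, MAGOH,
JAK1, NRAS) and two on 19q (CCNE1, PPP2R1A), eight values pooled
gene-weighted. A case is called co-deleted when the pooled score falls
**strictly below** a cutoff, default **1.65** (linear copy number; diploid =
2.0). The gene-weighted pooling means the 1p genes dominate 3:1; the
alternative (mean of the two arm means) is available via `pooling="arm"`.

The cutoff can be re-derived against a reference modality (interphase FISH)
with `calibrate_cutoff` / `CodeletionCaller.fit`: every midpoint between
adjacent distinct scores is evaluated as a threshold for the
"low-score-is-positive" classifier, and the chosen cutoff maximizes
Youden's J = sensitivity + specificity − 1, ties broken toward the larger
threshold. The sweep is exhaustive, so it provably agrees with brute-force
enumeration (property-tested on small instances).

Assumptions: copy-number estimates are on a linear scale centered at 2.0 in
diploid regions; arm-level events affect all panel genes on the arm
coherently (focal events on single genes will pull the pooled mean less than
a whole-arm loss); at least one gene per arm must be present — co-deletion
is never claimed from a single arm.

A note on calibrated-cutoff variability: with co-deleted scores near
1.17 ± 0.13 and non-codeleted scores near 2.0 with heavier spread, the
Youden-J maximum sits at the midpoint just above the highest co-deleted
score. Across seeded synthetic cohorts the chosen cutoff therefore ranges
over roughly 1.3–1.65 (band asserted in the tests at ≥ 95% of seeds in
[1.3, 1.9]); the fixed default of 1.65 is retained as the decision boundary
because sensitivity is the binding constraint in this setting.

## EGFR amplification vs chromosome-7 gain

High-level EGFR amplification (tens to hundreds of copies, often episomal)
and broad chromosome-7 polysomy both raise the EGFR copy number but have
different diagnostic weight. The caller computes the ratio of the EGFR copy
number to the mean of the remaining chromosome-7 panel genes (default
background set BRAF, CDK6, MET, SMO) and calls, with defaults:

* **amplified** — EGFR CN ≥ 4.0 **and** ratio ≥ 2.0 (mirroring the FISH
  criteria of > 4 mean EGFR signals/nucleus and EGFR/CEP7 ratio > 2);
* **chr7_gain** — not amplified and background mean ≥ 2.5;
* **no_alteration** otherwise.

Exact definitional thresholds separating gain from amplification are not
settled in the field; these defaults are documented heuristics and fully
configurable (`EGFRThresholds`). A raised EGFR with ratio near 1 (e.g. CN
2.7–4.6 at ratio 1.0–1.35) is classified as chromosome-7 gain, never as
amplification.

## CDKN2A

Single-copy loss is called at CN ≤ 1.3 and homozygous deletion at CN ≤ 0.7
(`CDKN2AThresholds`, configurable). The thresholds place typical intact
class means (~1.9) and deeply deleted classes (~1.1 with a focal-deletion
tail) on opposite sides of the loss boundary. When other 9p panel genes are
configured (default JAK2) and are concurrently below the loss threshold, the
event is flagged `broad_9p` (putative arm-level loss rather than focal
deletion). Absent copy number yields `not_assessed`; CDKN2A coding variants
are carried through regardless.

## IDH / TP53 interpretation and predicted IHC phenotypes

IDH pathogenicity is a configurable hotspot table, defaulting to IDH1
codon-132 missense (R132H/C/S/G/L/V) and IDH2 codon-172 missense
(R172K/M/W/G/S/H). Any other IDH1/2 change is `vus_only` — never silently
pathogenic. The predicted mutation-specific IHC is positive exactly for
IDH1 R132H (the stain sees no other variant), so predicted stain positives
are a subset of sequencing mutants by construction.

The predicted p53 IHC score encodes staining biology: no TP53 variant → 1
(wildtype pattern); any missense or in-frame deletion → 3 (stabilized
protein, strong labeling; missense dominates compound genotypes); purely
truncating (nonsense/frameshift) → 0 (absent epitope). Splice-site-only
genotypes are mapped to 0 on the same absent-protein reasoning; this mapping
is a heuristic, since observed splice variants co-occur with wildtype-like
staining in some tumors. Score 2 (ambiguous staining) exists only as an
observed IHC category and is never predicted.

ATRX status is predicted, not measured (the panel does not cover ATRX),
from the mutual-exclusivity structure of adult diffuse glioma: IDH-mutant +
co-deleted → preserved; IDH-mutant, non-codeleted, TP53-mutant → loss
predicted; IDH-mutant without TP53 → preserved; IDH-wildtype adult →
preserved; pediatric or H3-altered → indeterminate (outside the adult
structure — H3 G34 tumors in particular often carry ATRX mutations despite
wildtype IDH). Co-deletion takes precedence over TP53 status for the rare
TP53-mutant oligodendroglioma.

## Integrated diagnosis

The rule engine applies the WHO/cIMPACT-NOW decision order on molecular
grounds alone: (1) IDH-mutant + co-deleted → oligodendroglioma; (2)
IDH-mutant, non-codeleted → IDH-mutant astrocytoma, grade 4 iff CDKN2A is
homozygously deleted, otherwise not gradeable without histology; (3)
IDH-wildtype adult with ≥ 1 molecular alteration → IDH-wildtype
glioblastoma when EGFR is amplified, or chromosome-7 gain co-occurs with
chromosome-10 loss (panel operationalization: chr7 background mean ≥ 2.5
and chr10 set mean ≤ 1.5, configurable), or an external TERT-promoter flag
is set; otherwise diffuse glioma NOS. Cases with no alterations at all, and
pediatric/H3-altered cases, are routed to non-glioma/unclassified.

Markers the panel cannot assess (TERT promoter, H3F3A, histology) are never
inferred: they enter only as optional external flags and are otherwise
listed in the `unassessed` output. Contradictory inputs (co-deletion with
wildtype IDH — a known copy-number false-positive mode) are flagged
discordant and labeled diffuse glioma NOS. Every grade-4 output lists its
triggering criterion, and withdrawing that criterion downgrades the output.

## Fusion annotation

Annotation is a pure lookup against a versioned YAML catalog
(partner-order-insensitive, case-insensitive names) carrying typical CNS
context and candidate targeted therapies with blood-brain-barrier flags
(among the defaults, only crizotinib is non-penetrant). Events absent from
the catalog are reported as not previously described in CNS tumors with an
empty therapy list. An RNA-QC failure propagates as "fusions not assessed",
never as "no fusion".

## Concordance statistics

Contingency tables retain exact integer cells; metrics (sensitivity,
specificity, PPV, NPV, accuracy) are kept as numerator/denominator pairs
and rounded only for display (one decimal, configurable). Metrics with zero
denominators are absent, not 0. The p53 ledger scores each observed IHC
score against its expectation (0 and 3 expect mutation, 1 expects wildtype,
2 always counts as a prediction failure). Group-mean comparisons use
Student's equal-variance unpaired two-tailed t (Welch behind a flag) and
one-way ANOVA, with no multiple-testing correction.

## Synthetic cohort generator

The generator emulates a 233-case single-institution cohort: 14
oligodendroglioma, 29 IDH-mutant astrocytoma, 112 IDH-wildtype astrocytoma,
11 pilocytic astrocytoma, 67 other. Class frequencies are cohort counts,
not population incidence — the simulator emulates this study design.

Copy numbers use a two-level noise model: one standard normal deviate per
case, scaled by each gene group's case-level sd (modeling shared case
effects such as tumor purity and ploidy, hence perfectly correlated across
arms), plus independent per-gene jitter. The variance split (default 80%
case-level) satisfies sd_case² + sd_gene²/n = sd², so the across-case sd of
the per-case arm mean equals the configured value exactly; values are
truncated at 0. Configured per-class arm parameters: oligodendroglioma 1p
1.15 ± 0.14, 19q 1.23 ± 0.18, 19p 2.22 ± 0.13; IDH-mutant astrocytoma 1p
2.04 ± 0.37, 19q 1.96 ± 0.29, 19p 2.22 ± 0.29; IDH-wildtype 1p 1.97 ± 0.16,
19q 2.24 ± 0.38, 19p 2.44 ± 0.39. CDKN2A class means: 1.94 ± 0.41 /
1.73 ± 0.68 / 1.09 ± 0.75 (the wide low-mean distributions are truncated at
0, which raises their realized mean by ~0.02). The error bars these values
derive from are interpreted as standard deviations, not standard errors.

Mutation co-occurrence: IDH mutation in all oligodendrogliomas and
IDH-mutant astrocytomas (~90% R132H, the rest drawn from
R132S/R132G/R132C/R172K); TP53 in 28/29 IDH-mutant astrocytomas, 2/14
oligodendrogliomas, 38/112 IDH-wildtype. Observed p53 IHC scores are
emitted through a confusion matrix conditional on true TP53 status
(mutated: 2/22/13/33 over scores 0–3; wildtype: 4/103/17/0). EGFR
amplification affects 35/112 IDH-wildtype cases (magnitude log-uniform in
[10, 100] copies); a further 35% carry the +7/−10 signature (chr7 ≈ 3.0,
chr10 ≈ 1.3). EGFRvIII appears in 19/112 IDH-wildtype cases,
BRAF-KIAA1549 in 5/11 pilocytic astrocytomas; RNA QC fails in 21/233.
Values not fixed by any printed source (1q arm 2.0 ± 0.2, non-glioma arm
sds 0.2, chr7-gain frequency, TP53 variant-class mix, ATRX IHC emission
rates 55% loss / 10% inconclusive) were chosen once as field-realistic and
are all exposed in `CohortConfig`.

What the generator does **not** emulate: tumor-purity gradients and
subclonality beyond the shared case deviate, heavy-tailed and multimodal
copy-number distributions (a focal-deletion mixture for CDKN2A is the main
omission), segment-level structure within arms, FISH measurement error on
the co-deletion reference (FISH labels equal truth), and read-level data.
Passing tests therefore demonstrate correctness of the calling logic under
the configured normal-family conditions, not performance on real clinical
distributions — in particular, real co-deleted tumors with low purity can
score much closer to the cutoff than the simulated class does.

## Numerical choices and degenerate inputs

* Strict `<` at the co-deletion cutoff; a score of exactly 1.65 is not
  co-deleted.
* ROC thresholds are midpoints between adjacent distinct scores plus ±∞;
  the chosen cutoff is always finite; single-class inputs are errors.
* Missing genes: group means use present genes with the missing count
  reported; an entirely missing arm is an error for co-deletion, a zero
  background mean is an undefined-ratio error for EGFR, and absent CDKN2A
  copy number is `not_assessed`.
* Degenerate group comparisons (any group n < 2, or both groups constant)
  are errors rather than NaNs.
* Problem sizes in tests and the acceptance script (200 seeded replicates
  for operating characteristics; 10,000 cases per class for parameter
  recovery) were chosen as the smallest sizes at which Monte-Carlo error is
  negligible relative to the asserted tolerances.

## Known limitations

The chromosome-7 background and chromosome-10 gene sets are
laboratory-configurable because the full panel composition on those
chromosomes is assay-version-dependent; the defaults are representative
panel genes only. The +7/−10 thresholds and the CDKN2A/EGFR cutoffs are
heuristics, not community-standardized definitions. The integrated
diagnosis deliberately stops at molecular evidence: grading that requires
histology returns `not_gradeable`, and entities outside adult diffuse
glioma are passed through as non-glioma/unclassified rather than
classified.
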