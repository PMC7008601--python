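# Methods

## Analysis model

The pipeline treats upstream database-search output (peptide-spectrum
matches already filtered to 1% FDR at peptide and protein level) as ground
truth evidence and performs no re-scoring, protein inference or
quantification. All downstream statistics are presence/absence:

* **Peptide identity** is the modification-stripped uppercase sequence;
  modified forms of the same sequence collapse to one unique peptide. This
  is the conservative reading of "unique peptides" for reporting, and the
  record layout keeps bracketed modification annotations if the caller
  prefers not to collapse them.
* **Protein identity** is the accession exactly as delivered upstream; no
  isoform re-grouping is attempted, since protein inference already happened
  in the search engine.
* **Replicate merging** defaults to union (evidence in ≥ 1 technical
  replicate counts). The source study reports one identification list per
  individual without stating a concordance requirement, so union is the
  permissive reading; intersection (evidence must appear in every declared
  replicate of the sample) is provided for sensitivity analyses. Union
  presence is a superset of intersection presence by construction, and the
  suite asserts this.
* **Detection threshold**: a protein is detected in a sample when
  ≥ `min_peptides` (default 1) distinct peptides remain. Single-peptide
  identifications are deliberately allowed — several reported candidates
  rest on exactly one peptide per patient.
* **Mean unique peptides** are averaged over *detected* samples only. This
  is the only denominator consistent with the reported example of a protein
  found in five patients with one identical peptide each and a mean of 1.
  Report means are rounded half-up to one decimal (2.25 → 2.3).

## Selection rule

A protein is a candidate for patient group *g* iff (1) it is detected in at
most `max_control_detections` control samples (default 1) and (2) in at
least `ceil(min_patient_fraction × |g|)` patient samples (default half).
Ceiling makes "at least half" well defined for odd group sizes and
reproduces "5 of 10" at n = 10. Each patient group is screened against the
same control group independently; detection in another patient group never
excludes a candidate (the reference results report PD detection counts for
AD candidates, so no cross-group exclusion was applied there either). The
candidate list is sorted by descending patient-group detection count, ties
by protein name. No significance testing or FDR control is attached to the
candidate list — the rule is a preset frequency filter, and attaching
p-values to it is out of scope.

Under independent per-sample detection with probability *p* the selection
probability has the exact form
`P[Bin(n_ctrl, p_ctrl) <= max_control] * P[Bin(n_pat, p_pat) >= min_count]`.
The acceptance suite checks observed rates on 10,000-protein simulations
against this closed form within a 99% normal-approximation band; the same
formula says a null protein with p = 0.2 everywhere passes with probability
≈ 1.2%, which is why a real screen of ~2,000 proteins is expected to carry
tens of frequency-compatible background proteins — the rule screens, it
does not confirm.

## Blocklist

The shipped blocklist encodes eight abundant-serum families as
case-insensitive name substrings (hemoglobin, haptoglobin, hemopexin,
immunoglobulin, keratin, apolipoprotein, albumin, complement) plus
gene-symbol prefixes (HB, HP, HPX, IGH/IGK/IGL, KRT, APO, ALB, C1Q–C9,
CFB/CFH/CFI/CFD/CFP). Family matching is deliberately broad: prefix rules
like `C2`–`C9` can catch non-complement genes (e.g. C9orf* symbols) on real
annotations, and the exact membership of the original study's removal list
is not published beyond the family names — so the file is user-editable and
every run logs the removed accessions for audit. Matching is evaluated
per protein against all three identifiers (gene prefix, name substring,
exact accession).

## Overlap and QC

Group membership for the Venn summary is detection in ≥ 1 sample of the
group, independent of candidate thresholds. All 2^k − 1 exclusive regions
are reported; `percent_common` is 100 × all-groups-common / grand total
rounded to the nearest integer (1042/1854 → 56). The positive-control QC
passes iff the spiked protein (kallikrein-6 by default, matched by accession
or gene symbol) is detected in every sample with at least the configured
number of peptides.

The published Venn marginals (three group totals, three group-unique counts,
the all-common count and the grand total) uniquely determine all seven
regions of a three-set diagram; `csfscreen.reference` solves that small
linear system and rebuilds a presence matrix realising it, rather than
hard-coding region counts.

## Cohort statistics

Sex is compared with Pearson's chi-square without continuity correction
(the convention that reproduces the reference cohort's printed p = 0.5853
for the 6/6/4 female split); continuous variables with tie-corrected
Kruskal-Wallis, degenerate all-equal input reported as H = 0, p = 1.
Dunn's pairwise test is computed from mean-rank differences with the tie
correction `sum(t^3 - t) / (12 (N - 1))`; the multiplicity adjustment is
configurable (`none`, `bonferroni`, `sidak`) and defaults to `none`,
because the adjustment used for the reference cohort's printed pairwise
values is not stated and cannot be inferred from them. Exact reproduction
of those pairwise p-values is therefore not claimed. Missing demographics
are typed missing and excluded pairwise; variables observed in fewer than
two groups (e.g. an ordinal score recorded for one group only) are skipped.

## Synthetic studies

The generator emulates the study conditions the analysis assumes: 3 groups
of 10 samples, technical duplicates, and four protein classes with
independent per-sample Bernoulli detection —

| parameter | default | role |
|---|---|---|
| `n_background`, `p_bg` | 2500, 0.35 | common proteins; calibrated so per-sample detections land in the observed 461–1192 range (median ≈ 950 in a pilot run) |
| `n_enriched`, `p_enriched`, `p_ctrl_low` | 50/group, 0.8, 0.02 | true group-specific antigens |
| `n_contaminant`, `p_contam` | 60, 0.9 | abundant-serum families; names embed family tokens so the default blocklist removes them with probability 1 |
| `replicate_concordance` | 0.8 | probability a peptide observation lands in all replicates rather than one |
| `peptide_mean` | 2.0 | per-detection distinct peptides ~ 1 + Poisson(mean − 1), truncated at the per-protein pool size (6); reported candidate means span 1–2.3 |
| `spike_peptide_range` | 9–13 | kallikrein-6 positive control, present in every sample |

Everything is drawn from one `numpy` Generator seeded by `seed`, so
generation → screening → report is bit-reproducible. Synthetic demographics
(younger controls, lower patient MMSE, an H-Y score only for PD-named
groups) make the cohort-statistics path exercisable.

What the generator does *not* emulate: spectra, intensities, retention
times, search-engine FDR behaviour, peptide-length/charge biases,
protein-protein detection correlations (co-complex antigens), and batch
effects. Passing tests therefore demonstrate correctness of the counting
and selection machinery under independent detections, not robustness to
correlated missingness in real IP-MS data.

## Numerical choices and limitations

* Ties in candidate ordering break by protein name; region keys join group
  labels in design order with `&`.
* Half-up decimal rounding is used wherever a printed-style report value is
  produced; internal values stay unrounded.
* The q-value filter keeps records with no q-value (the upstream filter is
  assumed already applied); lowering `q_max` can only remove detections.
* Wide presence-mark tables without peptide rows record presence only;
  peptide statistics are flagged unavailable (`NA` in reports), never
  fabricated as 1.
* The per-candidate peptide fixtures built from the published group-level
  table reproduce detection counts and total-unique exactly; per-sample
  peptide counts below the group level are not recoverable from group
  summaries, so printed means are only approximated there.
* Simulation sizes in the test suite (10,000 proteins for the binomial
  oracle checks, hundreds for end-to-end runs) were chosen as the smallest
  sizes at which the 99% analytic bands are meaningfully narrow.
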