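# csfscreen

Presence/absence screening of immunoprecipitation mass-spectrometry (IP-MS)
identification tables for candidate autoantibody biomarkers.

## The problem

Autoantibodies in a biofluid such as cerebrospinal fluid (CSF) can be
profiled without an *a priori* target list: antibodies are captured on
protein-G beads, incubated with a tissue protein extract, and the co-captured
cognate antigens are identified by shotgun LC-MS/MS. The readout per sample
is a list of identified proteins (with their supporting peptides), not an
intensity — so the downstream statistics are presence/absence at the group
level. This package implements that downstream analysis for a case/control
cohort design (e.g. 10 headache controls, 10 Alzheimer's, 10 Parkinson's
CSF samples, run in technical duplicates):

1. **Replicate merging** — technical duplicates are merged per sample
   (union by default, intersection available).
2. **Presence matrix** — a protein × sample boolean detection matrix with
   per-(protein, sample) distinct-peptide sets. A protein is detected when
   ≥ `min_peptides` (default 1) distinct peptides remain after the optional
   q-value filter.
3. **Blocklist filtering** — abundant serum proteins prone to non-specific
   bead binding (hemoglobin, haptoglobin, hemopexin, immunoglobulins,
   keratins, apolipoproteins, serum albumin, complement) are removed by a
   shipped, user-editable family rule file.
4. **Candidate selection** — the two-part group-frequency rule. A protein
   is a candidate antigen for patient group *g* iff

   *n*<sub>control</sub> ≤ *c*  and  *n*<sub>g</sub> ≥ ⌈*f* · |g|⌉

   with defaults *c* = 1 (at most one of 10 controls) and *f* = 0.5 (at
   least half of the patients, 5 of 10).
5. **Reporting** — a per-candidate table (individuals identified, total and
   mean unique peptides per group), a Venn overlap summary of the group
   protein sets, a spiked positive-control QC (kallikrein-6 / hK6, expected
   in every sample with 9–13 unique peptides), and cohort demographic
   statistics (chi-square; Kruskal-Wallis with Dunn pairwise post-hoc).

A seeded synthetic-study generator (`csfscreen.simulate`) produces complete
studies — manifest, identification table, truth labels — with background,
group-enriched and contaminant protein classes, so every stage and the
selection rule's operating characteristics are testable without downloads.
Under independent per-sample detection with probability *p*, the expected
selection rate has the closed form
P[Bin(*n*<sub>c</sub>, *p*<sub>c</sub>) ≤ *c*] · P[Bin(*n*<sub>p</sub>, *p*<sub>p</sub>) ≥ ⌈*f n*<sub>p</sub>⌉],
which the test suite uses as an exact oracle.

## Worked example

```bash
python analysis/01_simulate_study.py     # seeded synthetic 3-arm study
python analysis/02_screen_candidates.py  # full screen + recovery scoring
python analysis/04_reference_checks.py   # selection rule on published tables
```

Step 04 prints:

```
AD candidates: 16; PD candidates: 0
absent in all controls: ['SERPINE2', 'FMOD', 'NQO1']
NQO1 in AD: n=5, total unique peptides=1
grand total antigens: 1854; common to all groups: 1042 (56%)
```

i.e. applying the default rule to the published per-group detection counts
selects 16 candidates in the AD group and none in PD; three candidates
(glia-derived nexin, fibromodulin, quinone oxidoreductase) are absent from
every control; and of 1854 antigens identified across groups after
blocklist removal, 56% are common to all three groups. Step 02 on the
synthetic study prints per-group sensitivity (fraction of truly enriched
proteins recovered) and false-candidate rate (fraction of background
proteins selected), e.g. `AD: sensitivity=1.000 false_candidate_rate=0.0252`.

The same pipeline is available as a CLI:

```bash
csfscreen simulate --outdir study --seed 1
csfscreen screen --manifest study/manifest.tsv \
    --identifications study/identifications.tsv --outdir results/run1
csfscreen cohort-stats --manifest study/manifest.tsv --outdir results/run1
```

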