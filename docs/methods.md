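# Methods

This note documents the models, rules and numerical choices behind
`magflux`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Pathway model and presence calling

A pathway is an ordered tuple of steps. Each step is a flat OR-of-AND
expression over KO identifiers: variants (isoenzymes or alternative
complexes) are alternatives; the required subunits of one variant must
all be present for that variant to count. The grammar deliberately
excludes nesting and parentheses: every pathway structure we needed is
expressible as OR-of-AND, and the flat form keeps presence evaluation
decidable by direct enumeration, with order preserved for round-trip
serialization.

Subunits marked optional (`-` prefix) are accessory components
(e.g. electron-transfer flavoproteins co-occurring with a
dehydrogenase). They are excluded from both presence detection and
expression aggregation; including them only when annotated would make
the statistic depend on annotation luck rather than biology, so the
conservative rule is applied uniformly.

Completeness is the detected fraction of *key* steps as an exact
`fractions.Fraction`, and the presence decision `completeness >=
threshold` is an exact rational comparison. This matters at the one
relaxed boundary in the packaged catalog: 10/11 ≥ 9/10 must hold while
9/11 < 9/10, and binary floating point cannot represent 0.9 exactly.
Thresholds read from YAML are converted via their decimal string, so a
catalog `threshold: 0.9` is exactly 9/10.

All steps are key by default. Non-key steps (e.g. transporter steps in
the LCFA-uptake and lactate modules, the hexokinase step of glycolysis)
must be flagged explicitly in the catalog; they are reported in step
expression but do not gate presence.

Presence is a purely genomic statement. "Expressed pathway" is a
separate, stricter notion — a positive presence call and positive
pathway activity — because encoding and transcribing are distinct
questions and conflating them hides exactly the functional-redundancy
signal the guild analysis is for.

## The packaged catalog

The packaged catalog holds 90 pathway definitions across eight
categories (depolymerization 7, sugar 16, amino acid 22, LCFA
β-oxidation 3, SCFA oxidation 5, central carbon 12, methanogenesis 4,
energy conservation 21). KO membership was curated from KEGG pathway
and module maps for each named route; step granularity follows KEGG
module conventions (one reaction per step, complexes as AND-joined
subunits). The file format — not the exact KO membership — is the
interface contract: users with their own curation supply a YAML file in
the same schema. Three structural facts are pinned by tests: exactly 90
pathways; the methylmalonyl-CoA pathway has exactly 11 steps and the
9/10 threshold; every pathway has at least one key step and all other
thresholds are 1.

## Expression aggregation

TPM is computed per sample over the entire merged ORF catalog (not per
MAG): `rate_i = count_i / length_nt_i`, scaled so each column sums to
10⁶. An all-zero sample column is an error, not a NaN column — it means
the sample has no usable signal and silently propagating it would
poison downstream shares. Partial (truncated) ORFs are retained
throughout; full-length status feeds only the QC metric
`full_length_fraction`.

Aggregation rules, bottom-up:

- **KO level** — TPM summed over all gene copies of that KO in the MAG.
  A gene annotated with k KOs contributes its full TPM to each; KO
  multi-labels are rare in GhostKOALA output and any splitting rule
  would be arbitrary.
- **Step level** — per variant, the arithmetic mean over required
  subunits, with missing subunits contributing 0 (an incomplete complex
  is penalized proportionally rather than silently renormalized);
  variant values are then summed, treating alternative enzyme systems
  like extra copies. The per-variant-mean-then-sum order is fixed; the
  alternative (pooling subunits across variants before averaging) would
  let a highly expressed single-enzyme variant be diluted by an
  unexpressed complex's subunit count.
- **Pathway level** — the arithmetic mean over ALL steps, silent steps
  entering as 0. For MAGs that pass the presence filter every step has
  at least one annotated gene, so the zero-fill only affects the
  diagnostic use of activity on non-encoding MAGs.

A KO shared by two steps of one pathway is counted in both; the catalog
validator flags such definitions so curators can restructure them if
double-counting is a concern. TPM columns are not renormalized after
aggregation — aggregated values are means/sums of TPM quantities and
keep those units.

## Guild analysis

Guild shares divide each eligible MAG's pathway activity by the guild
total (×100). Eligibility requires a positive presence call, so
expression from stray single-gene hits in non-encoding MAGs never
claims a share of the guild. An all-zero guild is reported with 0
shares and an explicit flag rather than NaNs. Replicate aggregation
uses the arithmetic mean and the n−1 sample standard deviation; a
single replicate reports sd as NA. Ranking is descending by mean share
with ties broken by ascending MAG id, making output order deterministic
under re-runs and row permutations. The active-population filter keeps
MAGs whose per-sample transcriptome fraction *strictly* exceeds the
threshold (default 1%) in at least one sample.

## Synthetic communities

The generator emulates a desk-scale anaerobic-digester
metatranscriptome with known truth:

- **Structure.** For every pathway a MAG encodes, one variant per step
  is chosen uniformly and every required subunit receives 1–2 gene
  copies, so the pathway is complete by construction and variant-level
  OR logic is exercised across MAGs. Decoy genes (half unannotated,
  half with off-catalog KOs) pad each MAG. ORF lengths are uniform in
  300–3000 nt; 86% of ORFs are complete at both ends, matching typical
  high-quality hybrid assemblies.
- **Counts.** Per gene and sample, NegativeBinomial with
  `mean = baseline_mean × length_nt/1000 × activity_multiplier` and
  dispersion 10 (variance = μ + μ²/10), the standard overdispersed
  RNA-seq model. Length-proportional means make TPM recover the
  configured activity structure; the baseline of 50 expected counts per
  kb-length gene puts typical genes well above shot noise without
  making ranking trivial.
- **Determinism.** A single seed drives hierarchical `SeedSequence`
  streams (profile, per-MAG structure, per-sample counts); identical
  configs yield byte-identical files.
- **Truth.** Ground-truth presence is the presence implied by the
  pre-dropout KO content — profile pathways are guaranteed, and shared
  KOs may genuinely complete further pathways, which is recorded as
  truth rather than mislabeled as error. True rankings order encoders
  by activity multiplier.

What the generator does *not* model: read-level error, rRNA carryover,
mapping ambiguity between paralogs, annotation errors other than
dropout, compositional coupling between MAG abundances, and
condition-dependent regulation. Passing recovery tests therefore shows
the inference machinery is correct and well-conditioned under the
stated noise model — not that real annotation pipelines are accurate.

## Problem sizes and checks

The test and acceptance workloads use deliberately small communities
chosen to exercise every code path: presence-boundary sweeps on the
11-step MMC definition; 1000 random count matrices for TPM column-sum
conservation (observed worst relative error ~1e-15); 1000 random
instances each for the step-aggregation brute-force oracle (1e-9
relative) and presence monotonicity; an 8-MAG community over the full
90-pathway catalog for presence-recovery F1; 100 seeded 6-MAG
communities with 4-fold-separated multipliers and 3 replicates for
top-3 ranking recovery; and byte-comparison of two same-seed pipeline
runs for determinism.

## Known limitations

- The catalog grammar cannot express nested alternatives
  (e.g. "(A+B),(C+(D,E))"); such modules must be flattened by
  enumerating variants.
- Pathway completeness is not corrected for genome completeness beyond
  the MMC exception; a 70%-complete MAG will systematically under-call
  strict pathways.
- Guild shares are normalized within eligible MAGs only; if most
  expression comes from MAGs failing the presence filter, shares
  describe a small guild faithfully but say nothing about the excluded
  expression.
- TPM is a within-sample relative measure; cross-sample comparisons
  inherit its compositional caveats, and no compositional correction is
  applied.
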