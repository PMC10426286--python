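# Methods

## The cascade

The prioritization model is a conjunction of three per-variant predicates —
panel membership, population rarity, predictor consensus — so the retained
set is independent of the order in which the filters are applied. The audit
trail, by contrast, attributes each removal to the *first* failing stage in
the fixed order panel → AF → predictor; the audit depends on that order and
the order is part of the contract.

Parameter defaults, with rationale:

- `af_threshold = 0.05` (fraction). The rarity cut is **inclusive**
  (AF ≤ 5%): the candidate table retains a variant whose ABraOM frequency
  is 4.96%, and boundary cases belong with the retained side. A variant
  reported by none of the four databases passes — absence from large
  population catalogues is itself evidence of rarity, and several retained
  candidates have no reported AF at all. Only *reported* frequencies are
  tested; there is no imputation.
- `min_damaging_predictors = 1` (count, of 13). Verdicts are three-valued
  (damaging / tolerated / unknown) and `unknown` never counts toward the
  rule, so a variant scored by zero predictors is excluded: the selection
  is of positively classified variants, not of unrefuted ones.
- `active_panels` defaults to all five panels (IEI, KD, COVID19, MISC,
  MISA). Panel symbols are uppercase-normalized; no alias resolution is
  attempted, because the whole analysis operates on plain symbols.

Clinical-significance labels are annotations carried through for
interpretation, never a filter stage. No zygosity or inheritance-model
filtering is applied: the cohort contains heterozygous carriers of
recessive-disease genes, and excluding them would change the published
carrier counts.

Variant identity is the triple (gene, transcript, HGVS c./n. change),
compared by string equality after whitespace stripping. There is no HGVS
normalization, no liftover and no genome-build awareness; genomic
coordinates in generated VCFs are placeholders on a fictitious contig.

## Descriptive conventions

Cohort percentages are **truncated**, not rounded, to one decimal
(29/30 → 96.6, 6/38 → 15.7), implemented in integer arithmetic to avoid
float edge cases. Quartiles use linear interpolation between order
statistics (on 30 ages this yields a Q3 such as 8.75).

The default complement-system gene set for carrier counting is the
complement pathway's present-study genes plus CFHR3 — the pathway table
lists CFHR3 among the present-study complement-family findings even though
the complement row's study column omits it; the nine-gene set is the one
that reproduces the published complement carrier fraction (14/30).

## Synthetic cohort

The generator emulates the analysis *inputs*, not the sequencing: a
30-patient roster, the 50-variant candidate table with its printed carriers
and allele frequencies, and `n_decoys` (default 200) decoy records split
evenly across three failure modes — common-AF (one AF drawn in
(0.051, 0.5]), benign (no damaging verdict), and off-panel (synthetic gene
symbol outside every panel). Decoy counts follow largest-remainder
apportionment of the mix fractions, carriers are 1–3 seeded random
patients, and all randomness flows through one `numpy` generator per call,
so identical specs give byte-identical files.

Per-predictor verdicts for the candidate variants were never published —
only the selection property that each has at least one damaging call — so
the fixture verdicts are synthetic: a deterministic hash of the variant key
seeds a draw of 1–4 damaging predictors. Ages are floor(gamma(2.5, 3))
clipped to [0, 17], a right-skewed pediatric-admission shape whose sample
median concentrates near 6 years.

What passing the recovery tests shows: the cascade implements its three
predicates exactly and the readers round-trip the annotations. What it does
not show: performance on real exomes, where decoys are not adversarially
labelled, annotations disagree between databases, and panel membership is
uncertain — none of which the generator models (no linkage, no population
structure, no annotation noise).

## Enrichment statistics

The published network analysis ran against a remote interaction database;
its edge counts and p-values are version-dependent, so the statistics here
are generic over any user-supplied scored edge list (thresholded at 0.4,
"medium confidence") and any flat term→gene map. No GO DAG propagation is
performed.

- *Density null*: expected internal edges of a k-node selection is
  ρ·k(k−1)/2 exactly; the p-value is the binomial upper tail with
  k(k−1)/2 trials at success probability ρ. Cheap and exact, but blind to
  degree structure.
- *Degree-weighted permutation null*: k nodes are redrawn without
  replacement with probability proportional to degree (the null used by
  degree-corrected network services); p = (1 + #{draws ≥ observed}) /
  (n_perm + 1). The add-one estimator never returns zero and is the
  reported p. Because the edge-count statistic is discrete, its p-values
  are only approximately uniform under the null; the calibration test uses
  a 60-node background with k = 18 so the statistic has enough distinct
  values for a Kolmogorov–Smirnov check at 500 replicates to be meaningful.
  Selections of fewer than two present nodes are rejected rather than
  scored.
- *Over-representation*: hypergeometric upper tail per term, BH step-up
  q-values across all tested terms (significance q ≤ 0.05 — the published
  "95% confidence" phrasing is read as a 0.05 level, the correction being
  unstated there), deterministic ordering by (q, p, term id). Empty terms
  are skipped with a warning.

The grouping of enriched processes into the 16 curated "major pathways" is
shipped as a static table (pathway × gene source), not recomputed: it is a
supervised judgement, not an algorithm.

## Problem sizes

All desk-scale: the cohort run is 250 records; the permutation-calibration
check uses 500 replicates of n_perm = 199 on a 60-node background
(≈15 s); exhaustive enumeration oracles are restricted to universes ≤ 12
genes and 6-node backgrounds, where the exact answer is computable by brute
force.

## Known limitations

- The panel fixture is reverse-engineered from the candidate table's panel
  column, so per-panel gene tallies beyond that column (and genes on panels
  but without candidates) are not represented.
- The tabular dialect stores only the gnomAD and ABraOM frequencies unless
  the extended columns are requested; ExAC / 1000 Genomes values survive
  round trips only through the extended table or the VCF dialect.
- The VCF dialect is minimal by design (site-level INFO annotations, one
  logical record per ALT) and its bit-exactness contract covers only files
  the package itself writes.
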