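# Methods

This note documents the models, parameter choices and numerical decisions
behind `iugrnet`, and what the synthetic benchmark does and does not show.

## Phenotyping

A fetus is IUGR iff its weight is strictly below
`mean(littermates) − k·SD(littermates)` with k = 2 and the sample SD
(n − 1). **Littermates exclude the index fetus**: including it would let an
extreme runt inflate its own threshold and the convention is genuinely
ambiguous in common usage; exclusion is the conservative reading and is the
one implemented. Litters with fewer than 4 fetuses are skipped with a
warning because a 2-SD rule on ≤ 2 littermates is statistically meaningless.
The boundary is strict ("more than two SD below"), so a fetus exactly at
the threshold is AGA. The rule is scale-equivariant (multiplying all
weights by c > 0 changes nothing), which the tests assert.

Discordant sib-pair selection is deterministic: within each litter, IUGR
fetuses (lightest first) are matched to the heaviest same-sex AGA
littermate still available; candidate pairs are ranked globally by
within-pair weight difference, ties broken by lexicographic fetus id, and
the top `n_per_group` (default 12) pairs are kept. The group weight
contrast uses Welch's unequal-variance t test, since group variances need
not match.

## Probe filtering

Presence filtering keeps probes detected (present-call mask true) in
**≥ 80%** of samples — the complement of excluding probes "present in less
than 80%". Detection calls are consumed as a boolean mask produced
upstream (DABG-style); the cutoff behind those calls is not re-derived.
miRNA probes with mature sequences ≥ 30 nt are removed (such records are
precursor, not mature, annotations). Both filters are idempotent and
commute, which is asserted as a property test. A quantile-normalization +
log2 utility is provided for raw synthetic intensities but is not part of
the reference path; the pipeline consumes already-normalized matrices.

## Differential expression

Per probe: `y = β0 + β1·group + β2·sex + u_dam + ε`, `u_dam ~ N(0, σ²_d)`,
`ε ~ N(0, σ²_e)`, REML-estimated (statsmodels MixedLM). The group effect is
reported as IUGR − AGA so "up in IUGR" is positive.

The group test is the **containment (within-litter stratum) F**: because
group and sex vary within litters, the test comes from the dam-absorbed
regression (dam indicators + group + sex), with denominator df
`n − rank([X | dam indicators])` (14 for the 24-sample, 8-dam design). The
within-litter contrast eliminates the dam effect exactly, so this F is
exactly F-distributed under the mixed model whatever the true dam variance
— unlike the REML Wald statistic, which is anti-conservative at n = 24
(measured 0.068 null rejection at α = 0.05 versus 0.056/0.048 for the
implemented test under zero/positive dam variance). When the REML dam
variance lands on the zero boundary (estimates below 1e−6 of the residual
variance, the optimizer's boundary signature), results fall back to the
ordinary two-way fixed-effects model so the degenerate case is
deterministic and matches an independent OLS computation to 6 significant
digits. Constant probes return effect 0, p = 1.

With exactly two group levels a Tukey–Kramer post hoc comparison reduces to
the single pairwise contrast: the studentized-range p at `q = √(2F)` equals
the F-test p, asserted in the tests, so a single F/p per probe is reported.

Significance policy: the miRNA track uses raw p < 0.05 (on arrays this
small no miRNA survives FDR control); the mRNA track uses
Benjamini–Hochberg FDR < 0.05. `bh_adjust` is the plain step-up rule,
cross-checked against statsmodels and against a literal brute-force
implementation.

## Duplex MFE target prediction

Regions are fragmented into 2000-nt windows stepping by 1950 (50-nt
overlap); the terminal fragment ends at the sequence end and may be short;
fragments shorter than the miRNA are emitted but skipped by the scanner. A
site fully inside an overlap scores identically from either fragment
(tested), and duplicate overlap hits are deduplicated by
(region, target start).

The scanner minimizes duplex free energy over all **intermolecular**
antiparallel pairings — no intramolecular structure, no target-site
accessibility. Energy = duplex initiation (+4.09 kcal/mol) + nearest-
neighbor stacking for adjacent pairs + length-dependent penalties for
bulges (≤ 8 nt) and internal loops (≤ 12 nt total); longer interruptions
are disallowed, as in standard loop-capped implementations. Pair formation
itself carries no term, so an exact full-length complement scores
`init + Σ stacks`, which the tests verify against the table by hand.

The stacking table (`data/rna_duplex_energies_v1.yaml`) uses the standard
RNA/RNA Watson–Crick nearest-neighbor values; G:U wobble entries are
curated approximations on the same scale (published wobble parameters are
sparse and context-dependent; only their ordering matters here). The
loader asserts strand-flip symmetry, WC/WC stacks ≤ 0, and nondecreasing
loop penalties. Because these absolute energies are not identical to any
external tool's tables, correctness is established by **equivalence with a
brute-force enumeration oracle** (all legal pairings, ≥ 500 random
instances with miRNA ≤ 12 nt and windows ≤ 25 nt) and by planted-site
recovery, not by numeric identity with a third-party program.

The helix (seed) constraint forces miRNA positions 2–7 (1-based, 5' end)
to pair with consecutive target bases. Wobble pairs are allowed inside the
forced helix by default (`wobble_in_helix` in the model file): the
constraint forces pairedness, not pair identity. Helix starts at base 1 or
2 are supported; deeper starts would need a mirrored 5'-side DP and are
rejected explicitly. A gene is called a target from its **single best site
across all three region classes**, reported only when MFE is strictly
below −25 kcal/mol. Scanning is restricted to opposite-direction
combinations (up-miRNA × down-gene, down-miRNA × up-gene), mirroring the
two-pass repression logic. No p-value is attached to sites: selection is
by the MFE threshold (an extreme-value calibration would need distribution
constants that are not part of this model). Coordinates are 0-based
half-open internally and 1-based inclusive in exported tables.

## Integration

Pearson correlation is computed across **all selected samples pooled over
groups** (stratifying by group is defensible but halves the sample size;
pooling reproduces the group-driven anti-correlation the design is built
to detect). Zero-variance vectors are excluded with a warning. The pair
threshold is r ≤ −0.3 **inclusive** (configurable). Multiple probes per
gene collapse to the most significant DE probe (ties by probe id), so
target counts are per gene. Every emitted pair satisfies all three gates,
asserted on every output.

## Enrichment

Upper-tail hypergeometric p (scipy's stable survival function), sets
intersected with the universe first, BH across all tested sets,
significance at FDR ≤ 0.05 inclusive. The universe is the **expressed
(filter-passing) gene set**, not the genome: a genome-wide background
inflates enrichment of anything expressed in muscle. Term grouping and
redundancy reduction offered by GUI tools are out of scope; the output is
the flat tested-set table.

## qPCR

`rel = 2^−(Ct_target − Ct_ref)`; the mRNA reference is the arithmetic mean
of the housekeeping Cts (ACTB, GAPDH) — equivalently the geometric mean of
their linear abundances — and the miRNA reference is the spike-in Ct. The
spike-in quantity (16 fmol, 2×10⁸ copies) is metadata only. Concordance
compares the sign of the IUGR-vs-AGA fold change per assay with the array
DE direction; assays with exactly equal group means are flagged and
excluded from the summary fraction.

## Synthetic data generator

The generator's defaults are the study conditions: one sire, **8 dams**,
litters of **10–14**, **2 growth-restricted fetuses per litter** (so eight
litters can supply 12 discordant pairs, as in the emulated design),
selection of **12 vs 12**. Weights are Normal(dam mean, 8 g) with dam
means Normal(175 g, 8 g); restricted fetuses get a **−62 g** shift — the
observed AGA−IUGR gap in the packaged cohort (175.96 − 113.60 g) and ≈ 7.8
within-litter SDs. The shift must be comfortably above 4 SD because a
second runt in the same litter contaminates the littermate mean/SD and
erodes the 2-SD rule's recall; at these defaults recovery is ≈ 95%.

Expression: log2 value = baseline U(6, 12) + signed group effect (±1 log2
on truth probes) + sex effect (±0.2 log2 on a random 10% of probes) + dam
effect N(0, 0.3) shared within litter + noise N(0, 0.2). Planted-pair
mRNAs additionally subtract β = 1.5 × the centered paired miRNA value,
producing the negative coupling the integration stage must detect. A 5%
fraction of probes is forced absent in 40% of samples to exercise the
presence filter; these are drawn from non-truth probes so the planted truth
stays interpretable (a simplification: real detection dropout is blind to
truth status). DE truth is skewed up for miRNAs (2/3 up) echoing the
asymmetry the design emulates; planted pairs use distinct genes.

Sequences: DNA on disk (FASTA, `>gene|region`), transcribed to RNA when
scanned. Region lengths straddle the 2000-nt fragmentation threshold
(3'UTR 600–2600, 5'UTR 150–450, CDS 900–3100 nt). Planted sites are the
**full reverse complement** of the mature miRNA embedded in the 3'UTR —
guaranteeing seed pairing and threshold passage under any reasonable
energy table — with offsets recorded in the truth object. Mature miRNAs
(20–23 nt) are constrained to ≥ 8 G/C bases: an AU-only 22-mer's perfect
duplex tops out near −15 kcal/mol and could never pass the −25 threshold,
so GC balance is a structural requirement of the planted-site
construction, not a tuning knob. qPCR Cts are generated as
`30 − log2 expression + N(0, 0.05)`, making full concordance a
construction guarantee.

Reproducibility: each generator stage draws from its own child stream
`default_rng([seed, stage])`, so identical configs give byte-identical
outputs whether stages run together or standalone (a per-stage refinement
of a single global stream, adopted so the spec of each operation is
independently reproducible).

What passing synthetic tests does **not** show: real arrays have
probe-level noise structure, batch effects, cross-hybridization and
truth-correlated dropout none of which are modeled; real binding sites are
partial duplexes, not perfect complements, so real-data recall at
−25 kcal/mol will be lower than the planted benchmark's.

## Pipeline and problem sizes

The pipeline validates its configuration before any stage runs, logs
before/after counts at every filter, writes fixed-format (`%.6g`) TSVs so
reruns are byte-identical, and records a manifest (config hash excluding
the output directory, seed, version, per-file row counts).

Default synthetic scale is 120 miRNA / 1500 mRNA probes — roughly a
tenth of the emulated arrays' filtered probe counts, chosen so a full
end-to-end run takes ~30 s and the 2000-probe null-calibration study about
a minute on one CPU. The acceptance script's oracle-equivalence checks use
miRNA ≤ 12 nt and windows ≤ 25 nt, where exhaustive enumeration is exact
and fast.

## Known limitations

- Denominator-df conventions differ across mixed-model software; p-values
  from other implementations may differ in the third decimal at n = 24.
- The energy table's wobble entries are approximations; absolute MFEs are
  comparable only within this model version (hence the versioned file).
- No intramolecular structure, accessibility, conservation or seed-type
  classification in target prediction.
- ORA treats gene sets as flat lists: no GO-graph propagation or pathway
  topology.
- qPCR efficiency correction (standard curves) is not modeled; `2^−ΔCt`
  assumes doubling per cycle.
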