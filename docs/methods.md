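# Methods

## Setting

`mqbench` quantifies how well label-free LC–MS proteomics workflows perform
and how comparable they are across laboratories, in the setting of a
round-robin (interlaboratory) study: several laboratories measure aliquots
of the same sample (e.g. plasma or CSF pools) in ~10 technical replicates,
at two measurement rounds (T1 before and T2 after protocol harmonisation).
The package consumes the tab-separated result tables a MaxQuant-style
search produces (`proteinGroups.txt`, `peptides.txt`, `evidence.txt`); it
never touches raw spectra and never re-runs a search engine.

## Data model and filtering

A *data set* is one laboratory × LC system × MS instrument × acquisition
mode × time point, with its replicate runs named
`<T#>_<Lab>_<LC>_<MS>[_<DDA|DIA>]_R<n>` (the acquisition segment is
optional and defaults to DDA). Three feature levels are tracked:

* **protein group** — indistinguishable proteins reported as one row; the
  semicolon-joined "Majority protein IDs" carry the accessions;
* **peptide** — a distinct (base) amino-acid sequence;
* **precursor** — a modified peptide sequence at a specific charge state.

Quantification cells equal to `0` are treated as *missing*, never as a
measured zero, because MaxQuant writes 0 for absent quantification.
Protein quantification prefers `LFQ intensity` columns and falls back to
plain `Intensity`; the choice is recorded in the bundle and the report.
Whether MaxDIA exports carry LFQ columns varies; treating the prefix as a
preference rather than a requirement covers both conventions.

Before any metric: reversed-decoy rows, potential contaminants, protein
groups only identified by a modification site, and spiked iRT calibration
peptides (default pattern `PROCAL`, substring-matched against accessions
and sequences) are removed; each removed row is tallied once, under the
first matching category in the order reverse → contaminant → only-by-site
→ spike-in, so tallies always sum to the input row count. Spike-ins are
removed before any "total ID" denominator is formed.

Replicates whose identification count collapses can be flagged as
outliers: a replicate is flagged when its ID count at a chosen level
(default: protein group) is strictly below a configurable fraction
(default 0.5) of the median count over all replicates of the data set.
Published round-robin analyses removed such runs by expert judgment; the
explicit rule makes the decision reproducible and reportable. Flagging
never mutates the data — dropping flagged runs is a separate, logged step
(`--drop-outliers`). Screening requires at least three replicates.

## Metrics

With `n` replicates per data set:

* **ID counts** — per replicate, the number of features with a non-missing
  quantification (protein group, peptide) or at least one evidence row
  (precursor); the median over replicates is the headline value.
* **Missed cleavages** — over *distinct* peptide sequences (union across
  replicates), the counts with 0/1/2 internal cleavage sites and
  `% zero = 100·n₀/total`. An empty peptide table yields a missing value,
  not 0.
* **Data completeness** — each feature's profile is the number of
  replicates observing it; a feature seen in all `n` replicates is a *full
  profile*, and `% full = 100 · (full profiles) / (all identified
  features)`.
* **Precision** — per feature the coefficient of variation across
  replicates, `CV% = 100·s/mean` with the sample (n−1) standard
  deviation; the reported statistic is the percentage of features with CV
  strictly below a threshold: 5% for precursor retention times, 20% for
  LFQ intensities. Features with fewer than two observations are excluded
  from the denominator rather than counted as failing, since precision is
  undefined for them. When one precursor has several evidence rows in one
  run (split peaks), their median RT/intensity represents that run.

The threshold comparisons are strict (`<`), so a CV exactly at the
threshold counts as not-precise; with continuous data the boundary case
has probability zero, but the convention matters for constructed tests.

Peptide-level metrics collapse modified forms to the base sequence;
precursors keep the modified sequence. A switch to stripped-sequence
precursors would only relabel features and is not currently exposed.

## Cross-data-set comparisons

* **Scaled median comparison** — for each metric, the medians over the T1
  and the T2 data sets (within one sample matrix; plasma and CSF are never
  pooled) are both divided by the larger of the two and multiplied by 100,
  so the larger round reads 100 and the difference is in percentage
  points. Both medians zero ⇒ the comparison is undefined (missing).
* **Overlap saturation** — each data set contributes the set of accessions
  expanded from the majority IDs of its protein groups present in at least
  `ceil(threshold/100 · n)` replicates (threshold 100 = full profiles;
  "at least 80%" with n = 10 means ≥ 8). Over an ordered sequence of data
  sets the running intersection (declining) and union (saturating) are
  reported with their ratio. The ordering is explicit caller input because
  intermediate values depend on it; terminal values do not. Accession
  expansion is used because laboratories group proteins differently, and
  it is the only comparison rule symmetric under regrouping — a documented
  design choice, not the only defensible one.
* **Biomarker matching** — a panel of accessions (plain text, one per
  line) is matched exactly (no isoform-suffix stripping) against each data
  set's full-profile accessions; matches carry the matched group's LFQ CV
  (when several full-profile groups list the accession, the group
  quantified in the most replicates wins, ties broken by higher median
  intensity, and the match is flagged ambiguous). Per accession, presence
  is the percentage of matching data sets, overall and per time point; the
  full-profile requirement already implies presence in every replicate,
  so data sets (not runs) are the denominator.

## Synthetic study generator

The generator emulates the statistical structure the metrics measure, with
known ground truth, so every pipeline stage is testable without deposited
raw data:

* **Inventory** — `n_proteins` target proteins, of which `shared_core_size`
  form a core visible to every laboratory and the rest are assigned
  lab-privately (round-robin); this plants the overlap structure, and the
  terminal intersection of full-profile sets recovers the core exactly
  when core detection is set to 1. Contaminant (`CON__`), decoy (`REV__`),
  only-by-site and `PROCAL` spike-in entries are injected with their
  flags; a fraction of lab-private groups carries a second majority
  accession to exercise grouped-ID logic (core groups never do, keeping
  the planted core size exact).
* **Peptides/precursors** — 1 + Poisson(mean−1) peptides per protein;
  missed-cleavage classes drawn from (p₀, p₁, p₂) (default 0.85/0.12/0.03,
  the in-solution-digestion regime); charges from a 2/3/4 distribution
  with an optional second charge state per peptide.
* **Detection** — each precursor carries a detection probability drawn from
  a Beta law (DDA default Beta(6,2); DIA Beta(16,3), tighter and higher,
  reproducing the DIA-completeness advantage) or a fixed p; per replicate,
  detection is an independent Bernoulli draw. T2 multiplies detection
  probabilities by 1.13 (clipped at 1), planting an identification gain of
  the ~10–16% order a successful harmonisation round shows.
* **Signals** — detected precursors get RT = base RT + N(0, σ_rt) (default
  0.25 min on a 60 min gradient) and intensity = exp(log-intensity +
  N(0, σ)), with σ = √ln(1+CV²) so the replicate intensity CV equals the
  configured target (default 15%). Peptide intensities are sums of their
  detected precursors and protein LFQ values sums of their peptides — no
  MaxLFQ-style normalisation is attempted. Consequently protein-level CVs
  in multi-peptide configurations are dominated by which peptides happen
  to be detected, as with un-normalised intensities in real data; tests
  that must control the protein CV law exactly use single-peptide,
  full-detection configurations.
* **Determinism** — all sampling flows from `numpy` generators derived from
  one seed; identical (config, seed) produce bit-identical files. Writing
  uses shortest-repr floats so the text round trip is value-exact.

What the generator does *not* emulate: chromatographic peak shapes,
match-between-runs, intensity-dependent missingness, shared peptides
between proteins, or MaxLFQ normalisation. Passing tests therefore
demonstrate the correctness of the metric computations and the plumbing
under controlled missingness/noise, not robustness to every artefact of
real acquisitions.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale studies — hundreds of
proteins, ~2 000–3 000 precursors, 4–10 replicates, 1–3 laboratories —
chosen so statistical recovery checks have tight exact-binomial bounds
while the whole suite runs in seconds. Statistical assertions use
simultaneous 99% bounds (Bonferroni-corrected exact binomial intervals, or
a Monte-Carlo oracle run under the same law plus its own sampling error).
Completeness thresholds convert to replicate counts with
`ceil(threshold·n/100 − 1e−9)`; the epsilon guards against binary-float
artifacts like `80·10/100` landing infinitesimally above 8. Medians use
the standard midpoint convention for even counts. Empty denominators
(no peptides, no evaluable features) propagate as missing values, never
as zeros.

## Limitations

* No FDR re-estimation — the 1% FDR is a property of the upstream search.
* No normalisation, imputation or differential abundance; all metrics are
  descriptive.
* No identifier mapping (gene symbols, isoform collapsing); biomarker
  matching is exact-string on accessions.
* The Spectronaut report dialect is not parsed; only the MaxQuant dialect
  (with a small alias map for adjacent versions) is supported.
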