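# Methods

## Scope and model

The package analyses paired IP/Total measurements from
co-immunoprecipitation of miRNA-induced silencing complexes: small-RNA
read counts for the miRNA side, two-channel microarray intensities for
the mRNA side, and 3'UTR sequence for target-likeness statistics. The
two inferential stages are exposed as model objects
(`MirnaEnrichment`, `TargetEnrichment`) whose `fit()` returns a results
object carrying estimates, p-values, calls and a `summary()`.

### miRNA enrichment

Counts are converted to read fractions per library with a pseudocount
(default 0.5) added to every count; the pseudocount exists only to keep
zero counts finite on the log scale and is configurable. Fractions are
normalized to the single smallest fraction across all libraries of the
analysis — one global reference, so every log2 relative abundance
shares a scale whose minimum is exactly 0. The IP-vs-Total contrast per
miRNA is a two-sided pooled-variance Student's t-test on log2
abundances across replicates (Welch available via `equal_var=False`);
calls are made at raw `p < alpha` (default 0.01) with the sign of
`Δ = mean_IP − mean_Total`. No multiple-testing correction enters the
calls; a Benjamini–Hochberg column is written for information.

Two consequences of the read-fraction scale are worth keeping in mind.
First, the scale is compositional: enriching a subset of miRNAs in the
IP necessarily depresses every other species' fraction, so null miRNAs
sit at a small negative Δ and a planted log2 effect of `e` is observed
as roughly `e − log2(Σ fractions after planting)`. Second, degenerate
zero-variance rows (all-identical log2 values in both groups) are
assigned `p = 1` when the means agree and `p = 0` otherwise rather than
propagating NaN.

### Target identification

Percent ranks use `(r − 0.5)/n` with average ranks for ties: symmetric,
mean exactly 0.5 per replicate, and free of the 0/1 endpoints that
break t-statistics. Ranks are computed per replicate over exactly the
probes reliably detected (both channels) in that replicate, *before*
any collapsing, and are never altered afterwards. Testability is ≥2
detected replicates (`min_reliable`). The per-probe test is one-tailed
Welch against the pooled ranks of all testable probes — Welch because
the group sizes (4–5 vs thousands) and variances are wildly unequal.
Probe→gene collapsing keeps the minimum-p probe, ties broken by larger
mean rank then lexicographic probe id, and is idempotent. The second
platform contributes one rank per gene as a fifth observation (and, by
default, to the background pool; `platform2_in_background=False`
disables that), after which p is recomputed; second-platform genes
absent from the main platform cannot reach two observations and are
dropped with a log entry. Enrichment is strict `p < alpha`
(default 0.001).

Note that under the Welch form, appending a fifth concordant value to a
near-zero-variance quartet can *raise* p (the degrees of freedom fall
from background-dominated to ~4); this is a property of the test
choice, not an error, and disappears under the pooled alternative.

### Seed-site statistics

A seed site is the reverse complement of mature nucleotides 2–8
(1-based, 5'→3'); the control is the reverse complement of the site
string, i.e. the seed heptamer itself in DNA form — an involution.
Matching is exact and overlapping; distinct 7-mers are counted
independently (for equal-width sites this equals one membership test
per UTR position, which is how it is implemented; a per-site scan
remains for mixed widths). `N` never matches. Multi-UTR genes resolve
to their longest annotated UTR. Densities are per 1000 nt aggregated
over the set (not per-gene averages), so they are invariant to gene
order and duplicates.

Mood's median test reduces each length vector to `n_points` (default
400) quantiles at probabilities `i/n_points` using the inverted-CDF
quantile type — chosen so that subsampling a vector of exactly
`n_points` values returns its order statistics unchanged — then tests
the above/at-or-below 2×2 table at the pooled grand median with a 1-df
chi-square, no continuity correction (Fisher-free, appropriate at
n = 800 grid points). Degenerate tables return p = 1 with a warning.

### Set statistics

Overlap p-values are upper-tail hypergeometric including the observed
count, `P(X ≥ k)` — the standard over-representation convention; set
members outside the universe are dropped and logged, not errored,
because published gene lists routinely exceed an array's universe. The
mean-percent-rank comparison tests set members against *all* testable
genes (the background includes the members) with a two-sided pooled
t-test.

## Synthetic-study generator

`SimulationConfig` defaults define the emulated design: 4 paired
IP/Total small-RNA libraries; 4 main-platform array replicates plus one
replicate from a second platform with exactly one probe per gene; 250
miRNAs; 3000 genes.

- **Counts**: baseline abundances log-uniform over 4 orders of
  magnitude; negative-binomial sampling (Gamma–Poisson,
  `var = m + φm²`, default dispersion φ = 0.1 — a typical
  biological-replicate overdispersion); library depth 2×10⁶ reads with
  per-library jitter in [0.75, 1.35]× so depths stay within 2× of each
  other. Planted effects multiply IP-fraction means by `2^±effect`
  before renormalization, so enrichment is compositional, not a depth
  artifact.
- **Arrays**: log-normal intensities (gene baseline 2^N(8, 1.5), probe
  affinity 2^N(0, 0.5), replicate noise 2^N(0, 0.3)); IP = Total ×
  2^(gene effect) × 2^N(0, 0.25) ratio noise; 1–2 probes per gene on
  the main platform (typical commercial-array density); independent
  per-channel detection dropout (default 5%).
- **UTRs**: lengths lognormal(μ=5.0, σ=0.6) → median ≈150 nt, matching
  the short 3'UTRs of nematodes; uniform ACGT background; target genes
  receive `planted_sites_per_target` non-overlapping 7-mer sites of
  randomly chosen input miRNAs, recorded in the ground truth.

All randomness flows from one seed through fixed named substreams, so
each layer is reproducible independently and jointly.

What the generator does *not* emulate: sequencing error and adapter
artifacts, cross-hybridization, intensity-dependent detection calls,
correlated probe effects, biased UTR base composition, isomiRs, and
any biological covariance between miRNA abundance and target identity.
Passing recovery tests therefore demonstrate the statistical machinery
under the assumed generative model, not performance on real platform
quirks.

## Problem sizes and calibration checks

The shipped checks run null calibration over ≥2000 simulated miRNAs
(type-I call rate at p<0.01 ≈ 1%) and 5000 genes (mean percent rank of
testable genes within [0.45, 0.55] — probe collapsing by minimum p
biases gene-level mean ranks slightly above 0.5, about +0.03 at 1–2
probes per gene), recovery over seeds with 300 miRNAs / 3000 genes per
replicate study, and seed-density separation over 20 independent UTR
universes. On the miRNA side, an average planted recall of ~0.80
(rather than ~0.9+) at effect 2.0 and φ = 0.1 is expected from first
principles: the compositional downshift reduces the realized contrast
to ≈1.7 log2 units, which at the log2-scale replicate SD floor
`sqrt(φ)/ln 2 ≈ 0.46` gives a pooled-t (df 6) power ceiling near 0.89
before the log-uniform low-abundance tail is averaged in.

## Known limitations

- The miRNA stage tests log2 abundances; with very low counts the
  t-test is only approximately calibrated (measured ≈0.9% at a nominal
  1%).
- Percent ranks assume pre-normalized array signals; no background
  correction or between-array normalization is performed.
- The seed analysis is 7-mer-exact only: no 6mer/8mer/7mer-A1
  taxonomy, conservation, or pairing thermodynamics.
- "Reliable signal" is taken as a boolean flag supplied with the data;
  deriving it from raw intensities is platform-specific and out of
  scope.
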