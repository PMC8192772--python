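# Methods

`coihap` implements the statistics used in single-locus haplotype surveys
of mtDNA barcode fragments — diversity summaries, neutrality tests,
mismatch distributions, AMOVA/Φ_ST, PCoA — together with two analyses
specific to concerted purine "hotspot" variation in a COI coding
fragment: key-string haplotype grouping with A→G polarity inference and a
positional covariance network, plus a QGRS-style G-quadruplex motif
scanner. This note records the models, the defaults and why, the
numerical choices, and what the synthetic generators do and do not
emulate.

## Alignment model and conventions

All analyses operate on an equal-length, already-aligned set of haploid
sequences over `{A,C,G,T,N,-}`. Coordinates are 1-based inclusive
throughout, so the hotspot sites are exactly the literature's 207, 282,
354, 420. Haplotypes are defined by exact string identity; `N` does not
wildcard-match (no mismatch tolerance is defined for collapsing, and the
modelled data contain no indels). For all distance-based statistics,
sites carrying `N` or `-` in either member of a pair are excluded from
that pair only (pairwise deletion).

## Diversity and neutrality statistics

* **Haplotype diversity** is Nei's unbiased estimator
  h = N/(N−1)·(1 − Σ p_i²); populations of size 1 report `NaN`
  ("not determined").
* **Nucleotide diversity** is reported twice, deliberately: `pi_raw`
  (mean per-site pairwise difference) and `pi_jc` (Jukes–Cantor
  d = −¾·ln(1 − 4p/3) applied per pair before averaging). Published
  tables for this kind of survey are ambiguous about which is printed —
  the caption may claim a JC correction while the printed value matches
  the uncorrected ratio — so both are always computed and `pi_raw` is
  used when matching printed two-sequence examples.
* **Tajima's D** uses the 1989 closed-form constants
  (a₁…e₂, re-derived literally in a test oracle) with θ_π = K, the mean
  pairwise difference count, and θ_W = S/a₁. Not determined for N < 4 or
  S = 0 (zero variance).
* **Fu's Fs** takes θ̂ = K (the mean-pairwise-difference estimator), sets
  S′ = P(K_alleles ≥ k_obs) under the Ewens sampling distribution
  P(k) = |s(N,k)|·θᵏ/θ^(N), and reports Fs = ln(S′/(1−S′)). Unsigned
  Stirling numbers of the first kind are computed by the
  |s(n+1,k)| = |s(n,k−1)| + n·|s(n,k)| recurrence entirely in log space,
  and the log-odds are formed from the two tail `logsumexp`s directly, so
  neither tail underflows first; ±inf can appear only on true underflow
  and is logged. k_obs = 1 or K = 0 is not determined.

## Mismatch distribution

The observed histogram counts pairwise differences over all unordered
pairs. Two expectation curves are attached:

* constant size: the equilibrium geometric form
  F(d) = θᵈ/(1+θ)^(d+1) at θ = K;
* sudden expansion: the exact two-epoch closed form
  F_j = F̂_j(θ₁)·P(j+1, τ(1+1/θ₁)) + e^(−τ/θ₁)·Σ_i Pois(j−i; τ)·F̂_i(θ₀),
  i.e. a pair either coalesces in the recent epoch (truncated geometric,
  regularised incomplete gamma weight) or survives past the expansion τ
  mutational time units ago and adds a Poisson(τ) load to a geometric(θ₀)
  pre-expansion component. The τ→0 and τ→∞ limits reduce to the two
  equilibria (tested).

(θ₀, θ₁, τ) are fitted by least squares on relative frequencies over a
documented deterministic grid — τ ∈ linspace(0, d_max+1, 33),
θ₀ ∈ linspace(0.01, max(2K, 1), 17), θ₁ ∈ {1, 10, 10², 10³, 10⁴} —
followed by a Nelder–Mead refinement from the best node in a
log1p-transformed, clipped parameter space; the refined optimum is kept
only if it does not worsen the grid optimum, so fitting is deterministic.
Both expectation curves are renormalised over the observed class range
and scaled to the pair count, so the three curves share one total.
Harpending's raggedness r = Σ (f_{d+1} − f_d)² is computed on the
relative-frequency curve with an implicit trailing zero class.

## AMOVA, Φ_ST and permutation testing

One-level AMOVA follows the classical sums-of-squares-from-squared-
distances decomposition with the convention of the standard haplotype
AMOVA software: the raw pairwise difference count *is* the squared
distance. Variance components use the unequal-sample-size coefficient
n₀ = (N − ΣN_p²/N)/(P−1); negative components are retained untruncated so
percentages can exceed 100% / fall below 0%, as they do in real
panmictic data. Φ_ST = σ²_among/(σ²_among+σ²_within). The p-value
permutes samples across populations and is observed-inclusive,
p = (1 + #{Φ_perm ≥ Φ_obs})/(n_perm + 1), bounded in [1/(n_perm+1), 1];
the default is 1000 permutations with an explicit seed. Pairwise Φ_ST is
the two-population AMOVA per pair; pairs involving a population of size
1 are not determined. A size-1 population in the global test only logs a
warning (it contributes no within-group sum) — surveys of rare species
routinely carry such populations.

## PCoA

Classical metric scaling: double-centre −½D² (elementwise square of the
supplied distances), eigendecompose, keep positive-eigenvalue axes
ordered by eigenvalue, with explained fractions over positive eigenvalues
only. Cross-checked against scikit-bio's implementation in the tests;
the implementation here is ~15 lines of linear algebra and keeps the
package's distance conventions explicit.

## Hotspot groups, polarity and covariance

Site classification tallies A/C/G/T states per column, by default one
vote per haplotype (the counting unit of the 71-polymorphic /
31-informative style of site count), optionally weighted by individuals.
Parsimony informativeness requires ≥2 states each carried ≥2 times.

Key-string groups concatenate a haplotype's states at the key sites.
The ancestral group is the one with maximal within-group haplotype
diversity weighted by individual counts — the standard
older-alleles-are-more-diverse argument; outgroup evidence is outside
this package's inputs, so an explicit `ancestral=` override exists and a
diversity tie raises rather than guessing. Remaining groups are ordered
by Hamming distance of key strings from the ancestral key, ties by
descending diversity then lexicographically. The chain is flagged
stepwise only when every consecutive pair differs at exactly one key
site; note the canonical four-group A→G chain is *not* strictly stepwise
(its last step flips two sites), and the flag reports that honestly.

"Covariance" between two sites is defined as the number of haplotypes
whose states fall in the same polarity class at both sites (both
ancestral/major or both derived/minor), reported with the frequency
ratio over haplotypes. This is an interpretive definition — the
literature using it does not write a formula — chosen as the simplest
concordance statistic consistent with reported count patterns; it is
cross-checked against a brute-force per-haplotype tally in the tests.
Haplotypes are the counting unit. Without supplied polarity, the major
state (ties toward the alphabetically smaller base) anchors the classes;
multi-allelic sites in a requested set are an error.

Codon annotation uses translation table 5 (invertebrate mitochondrial,
the standard table for this gene) with frame auto-detection by internal
stop minimisation over all sequences; if even the best frame has stops
in >5% of codons the error suggests a wrong strand or code. A
polymorphic site is synonymous iff every observed state yields the same
amino acid in every haplotype's own codon context.

## G-quadruplex scanning

Candidates are every ordered choice of four maximal G-runs of length ≥
`g_min` whose three inter-run gaps lie in `[loop_min, loop_max]`;
enumeration is exhaustive (equal to a brute-force oracle in tests) and
loops may contain sub-threshold G-runs. Defaults: `g_min=2` (canonical),
`loop_max=20`; `g_min=1` admits single-G "new type" tracts, and
`loop_max` must be raised to ≥21 to represent the longest reported loop
(N₂₁) — deliberately not the default, so non-canonical settings are an
explicit user choice. Scanning is on the given (mRNA-sense) strand only.

The score is an artifact-defined surrogate (the published QGRS tools do
not disclose their formula): w_t·(min tract −1) − w_m·mean(loops) −
w_r·(max−min loops), defaults (20, 1, 1), monotone in tract depth and
loop compactness, weights config-exposed.

Non-overlapping selection runs up to `max_passes` (default 10) passes;
each pass greedily extracts a maximal pairwise-disjoint set (highest
score, ties leftmost then shortest; overlap = any shared base) from the
candidates not selected in earlier passes. Within-pass disjointness and
monotonicity of the total count in `max_passes` are tested properties.
A motif is "linked" to a hotspot site iff the site lies inside its span.

## Synthetic generators

`simulate_expansion_alignment` plants, rather than samples, the
structure the analyses are tested against, so recovery tests are exact:

* a random in-frame coding backbone (table 5, frame 1, no internal
  stops; no TA*-initial codons so planted third-position transitions can
  never create stops), with key-site codons drawn from fourfold-
  degenerate families so both key states are synonymous;
* key-string groups at configured haplotype counts. The defaults plant
  the four canonical groups at 35/12/1/8 *plus* two single-haplotype
  variant key strings (A-A-A-G, A-G-A-A), closing the total at 58
  haplotypes while keeping the canonical sizes — the modelled survey
  itself reports within-ancestral-group variant key strings;
* an exact site budget instead of a Poisson mutation rate: shared
  (parsimony-informative) sites with ≥2 carriers and singleton sites are
  planted one-per-codon, transition-only, biased 9:1 toward third codon
  positions, in numbers chosen to yield exactly the configured 71
  polymorphic / 31 informative columns. Exact counts are the point of
  the recovery tests, and a Poisson law cannot guarantee them;
* a skewed individual-per-haplotype law: the base haplotype of the most
  derived group is dominant (~19% of individuals, emulating a dominant
  derived haplotype), ~74% of haplotypes are singletons, and the
  remaining counts decay geometrically (ratio 0.75), concentrated in the
  *more derived* eligible groups so that within-group diversity
  decreases along the planted path and polarity inference is decidable;
* panmictic population assignment at `population_mixing=1` (uniform,
  independent of haplotype), degrading to haplotype "home" populations
  as mixing → 0.

What it does **not** emulate: recombination, back-mutation or
multi-state sites, indels, sequencing error/ambiguity codes, realistic
geographic sampling imbalance, or genealogical correlation between the
planted sites (sites are independent given group membership). Passing
recovery tests therefore demonstrates the *operations* are correct on
data with the right marginal structure, not that real data would show
these exact values.

`simulate_coalescent` is an infinite-sites simulator used only to
calibrate the neutrality tests: the constant model is the standard
Kingman coalescent (validated against E[S] = θa₁ and an external
simulator during development); the star model joins all lineages at one
node with branch length 1 so E[pairwise difference] = θ matches the
constant model while every mutation is a singleton — the canonical
expansion caricature. Mutations map to distinct sites of a fixed-length
sequence; overflow is an error rather than silent site reuse.

Determinism contract: every generator is a pure function of its config
(same seed ⇒ byte-identical output); replicate suites derive child seeds
(< 2³¹) from one parent seed.

## Problem sizes and defaults used in the checks

Calibration suites use 200 replicates (n=30, θ=5 constant; n=50, θ=5
star), the panmixia check 20 dataset replicates with 199-permutation
AMOVA, and the scanner oracle 50 random sequences ≤100 bp — sizes at
which the Monte-Carlo error of each asserted quantity is comfortably
inside its asserted band. `scripts/acceptance.py` re-runs the same
computations (999 permutations for the single reported AMOVA) and
finishes in seconds.

## Known limitations

* Fu's Fs significance is not computed (no coalescent null resampling);
  only the statistic itself.
* The mismatch fit is least-squares, not the generalised
  least-squares/bootstrap machinery of dedicated software; raggedness has
  no attached p-value.
* AMOVA is one-level (populations within total); no regional hierarchy.
* The covariance definition is interpretive (see above) and reported as
  such.
* The scanner scores by a surrogate formula; absolute scores are not
  comparable to published G-scores, though orderings under default
  weights are sensible (deep tracts ≫ long uneven loops).
* `infer_transition_order` uses diversity only; with outgroup data the
  override flag should be preferred.

## Pipeline and interfaces

`coihap.pipeline.run_pipeline` sequences the full analysis (collapse →
diversity/neutrality → mismatch → AMOVA/pairwise Φ_ST → PCoA → site
classes → groups/polarity → covariance → G4 scan) and writes a report
bundle (TSV/JSON/GraphML) whose files carry the package version, the
seed and a hash of the scientific configuration; reruns are
byte-identical, single-population inputs skip AMOVA with a recorded
reason, and stage failures name the stage. The numbered scripts under
`analysis/` are thin narrative drivers over the same library calls; they
and the library functions are the command-line surface of the project.
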