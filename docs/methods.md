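# Methods

This note documents the statistical procedures implemented in `mirstab`,
the synthetic data model used to validate them, and the numerical and
design choices made where the procedure left room.

## Pipeline model

The unit of analysis is a probe-by-sample matrix of non-negative integer
molecule counts from an nCounter-style assay, with probe classes
(endogenous miRNA, housekeeping mRNA, positive control, negative control)
and sample groups (here thyroid, glioma, bone marrow, plus the *pooled*
union of all samples). Probes that measure the summed content of two
miRNAs (names joined by "+") are treated as single atomic probes.

**Filtering.** Within a group of n samples, probe p is excluded iff
`#{s : c_ps < 50} > n/2`, both inequalities strict; with n = 4, two
low-count samples retain the probe, three exclude it. Only endogenous
miRNAs are subject to (or returned by) the filter. The pooled group
applies the rule over the union of samples, not the intersection of
per-group survivors. There is no negative-control background
thresholding: the pipeline takes raw counts as given.

**Normalization.** `x_ps = log2(max(c_ps, 1)) − log2(Σ_{q∈N} c_qs)`.
Normalizer totals are plain sums of molecule counts — deliberately not
geometric means — and are used unfloored; a zero total is an error. The
numerator floor of 1 only matters for retained probes that still hit a
zero count (rare after the 50-molecule filter); the number of floored
cells is recorded on the result. "All miRNAs found" is read as all
endogenous miRNAs surviving the group's filter; "75 most represented" is
the top 75 retained miRNAs by total count over the group's samples, ties
broken by probe id, resolved *after* filtering. All four normalizers are
within-sample, so scaling a sample's counts by a constant leaves its
normalized values unchanged, and under total-miRNA normalization the
per-sample shares `2^x` sum to exactly 1 when no floor triggered.

**Variability and ranking.** SD uses the n−1 denominator. IQR uses
linear interpolation between order statistics at position
h = (n−1)p + 1 (numpy's default quantile rule). MADM is the *mean*
absolute deviation from the *median*. Ranks are ascending (1 = least
variable) with average ranks for ties, so rank sums can be non-integer
under ties; integer rank sums arise when no ties occur. The combined
rank sum uses exactly two strategies (housekeeping and total miRNA) —
4 measures × 2 strategies = 8 ranks; the minimum attainable rank sum is
8. Rank-sum ties are ordered by SD under the last ranking strategy, then
probe id, making the table deterministic. Per-(measure, strategy) values
for all four strategies are available via `stability.measure_frame` for
inspection beyond the two ranking strategies.

**Paired dispersion tests.** With composite series x (top 5, mean of
logs) and y (next 5) over the same samples:

* Grambsch: D = x − y, S = x + y, `u_i = (D_i − D̄)(S_i − S̄)`,
  `T = √n·ū/s_u`, two-sided standard-normal p. Its sign equals the sign
  of the Pitman–Morgan correlation corr(D, S); H0 is var(x) = var(y).
* Bonett–Seier: `a_i = |x_i − med(x)|`, `b_i = |y_i − med(y)|`,
  `z = ln(ā/b̄)/SE`, `SE² = [var(a)/ā² + var(b)/b̄² − 2cov(a,b)/(āb̄)]/n`,
  two-sided standard-normal p; H0 is equal mean absolute deviations from
  the median.

Both tests require n ≥ 3 pairs and error on smaller inputs rather than
returning unstable asymptotics. Exactly proportional inputs
(y = a + b·x) zero the Bonett–Seier SE analytically; the implementation
returns the deterministic limit (z = 0, p = 1 for a pure shift, where
the MADM ratio is 1; ±∞ with p = 0 for a genuine scale change) behind a
relative floor of 1e-10 that absorbs floating-point cancellation.
Identical series make the Grambsch denominator zero and raise a
degenerate-input error. Both statistics use the asymptotic normal
reference, so null p-values at n = 30 are uniform only to within a few
percent of CDF deviation; measured type-I error at α = 0.05 is ≈ 0.056
(Grambsch) and ≈ 0.050 (Bonett–Seier) — the property test allows a
Kolmogorov–Smirnov statistic up to 0.06 for this reason.

The top-5/next-5 probe sets are fixed once by the combined rank-sum
ordering and the composites are then recomputed under each normalization
strategy of interest (the probe sets do not change between strategies).

**Permutation test on rank concordance.** The union list L of the two
strategies' five least-variance miRNAs carries within-list ranks 1..|L|
per strategy, assigned as serial numbers after sorting by (variance,
probe id) — always a permutation, with a deterministic tie-break. The
statistic is `T = Σ|rank_A − rank_B|`; "five best" selection uses the
*variance* of log2-normalized values, not the four-measure rank sum. The
exhaustive p-value is exact for |L| ≤ 10: relabeling the list by the
fixed ranking reduces T under a uniformly permuted opponent to
`D(π) = Σ|i − π(i)|` with π uniform on S_n, and the distribution of D is
computed by dynamic programming over subsets of used rank values
(2^n states; identical to enumerating all n! permutations and verified
against enumeration in tests). Holding one ranking fixed and permuting
the other is equivalent, by symmetry of T, to permuting both. The
maximum attainable T is ⌊n²/2⌋. Monte-Carlo mode uses the add-one
estimator (count + 1)/(n_mc + 1) with a recorded seed. The six pairwise
p-values are BH-adjusted (step-up; implemented over
`statsmodels.multipletests` and property-tested against the literal
step-up definition).

## Synthetic data model

The generator emulates an nCounter miRNA panel so that every stage has a
known answer. For probe p and sample s, the expected count is
`μ_p · f_s · exp(ε_ps) · 2^{δ_pg}` where:

* `f_s` is a per-sample (lane) size factor, lognormal with SD 0.25 log2
  units — the scale of lane-to-lane binding-density variation;
* `μ_p` is the base abundance: expressed miRNAs draw log2 μ from
  N(9.5, 1.2) (typical counts ≈ 180–5000, nearly all passing the
  50-molecule filter), non-expressed miRNAs and negative controls sit at
  the background mean 4, housekeeping mRNAs at 5 000–15 000, and the six
  positive controls on a 4-fold ladder from 24 to 24 576;
* `ε_ps` is a lognormal biological term with SD 0.05 (planted stable
  miRNAs), 0.4 (planted variable miRNAs) or 0.2 (expressed miRNAs in
  neither class, in configurations that have any);
* `δ_pg` shifts each variable miRNA by ±1 log2 unit in exactly one
  randomly chosen group — group-dependent expression.

Counts are negative-binomial with `var = μ + 0.005·μ²` (technical CV
≈ 7% at high counts, Poisson-dominated at low counts). Setting
`dispersion = 0` switches to the deterministic limit (counts = rounded
means), which makes noise-free exactness tests meaningful; a negative
binomial with dispersion → 0 would still carry Poisson noise. A single
PCG64 stream seeded from the config draws everything in a fixed order
(structure, size factors, abundances, group effects, counts), so output
is bit-reproducible given the seed.

Default study shape: 800 miRNA probes, 200 expressed, of which 5 are
planted stable and 195 variable (expressed probes split exhaustively
into the two classes, mirroring the binary stable/varying picture that
motivates reference-gene screening), across three groups of 12 samples
(36 total). The `paper_like` fixture widens this to 32/12/12 samples;
the `tiny` fixture (20 miRNA probes, 2 × 4 samples) keeps unit tests
fast. Control complements are always 5 housekeeping + 6 positive + 8
negative.

What the simulator does **not** model: probe-specific hybridization
efficiencies, codeset-version differences, background cross-talk between
probes, sample-quality gradients, or correlated miRNA co-regulation.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and recovers planted structure under realistic count noise — not
that any particular real tissue has stable miRNAs, nor which ones.

## Measured behavior at default settings

All figures below are computed by the test suite / `scripts/acceptance.py`
at run time, at these problem sizes:

* Filter ≡ brute-force oracle on 1 000 random boundary-heavy matrices.
* Monte-Carlo permutation p within 3 binomial SEs of the exact p at
  100 000 draws.
* Paired-test type-I error at α = 0.05 under a bivariate-normal null
  (ρ = 0.5, n = 30, 20 000 replicates): both within [0.035, 0.065].
* Planted stable-set recovery: top-5 of the rank-sum table contains ≥ 4
  of the 5 planted stable miRNAs in ≈ 100% of 100 simulated studies.
* Top-5 vs next-5 dispersion gap: both paired tests reject at α = 0.001
  in ≈ 91–93% of 200 simulated studies. Two effects bound this rate:
  the Grambsch statistic's asymptotic ceiling near √(n/2) ≈ 4.24 at
  n = 36 caps its power at ≈ 97% at this α even for arbitrarily large
  variance gaps, and positions 6–10 of the ranking are the least
  variable of the 195 variable probes, so their realized composite
  dispersion is deflated by selection. The Bonett–Seier side alone
  rejects in ≈ 99.5% of studies.

## Known limitations

* The two dispersion tests rely on asymptotic normal references; below
  ~20 samples their p-values should be treated as approximate.
* The exhaustive permutation test is limited to union lists of 10 (the
  maximum that two 5-entry top lists can produce); larger k requires
  Monte-Carlo mode.
* Multi-codeset harmonization is out of scope: a count matrix carries a
  single probe set, and the run manifest records the codeset labels
  present.
* RCC reading covers the Code_Summary/Sample_Attributes sections of
  standard per-sample RCC text files; vendor QC fields are ignored.
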