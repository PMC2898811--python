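# Methods

## Model and assumptions

The region is a fixed partition into `I` administrative cells with known
populations `n_i` (optionally per stratum, `n_is`), total `n`. Event data
come in one of two forms: a case-by-event-count histogram `c_iy` (number of
cases in cell `i` with exactly `y` events, `y = 1..Y`) or aggregate event
totals `v_i` only. The null hypothesis for every test is that each
individual is equally likely to have events, independent of other
individuals and of geography; under it the individuals observed in any
sub-population are an exchangeable sample without replacement from the
region.

Given a tested cell `i` and event cluster size `k*`, the statistic
`L_i` is the smallest number of nearest neighbours whose combination with
`i` holds at least `k*` events; the p-value is `P(X >= k*)` where `X` is
the null count in a sample of size `m = n_{i:L_i}` (per-stratum sizes for
stratified tests). Small `L_i` means many events near cell `i`.

### Null families

* **Cases (`hc`)** — `X` = number of cases among `m` of `n` individuals:
  hypergeometric with `c` cases total.
* **Exact events (`ee`)** — individuals fall in classes by their number of
  events (`C_y` cases with `y` events, `n - c` with none); `X = Σ y·r_y`
  for a without-replacement sample: a multiple hypergeometric. We compute
  the joint weight `W[t, x]` of sampling `t` class members carrying `x`
  events by convolving the classes one at a time, normalizing each class
  kernel `C(C_y, r)` to a Binomial(`C_y`, ½) mass so the accumulator stays
  inside [2^-c, 1] in linear space; the `m`-dependent factor
  `C(n-c, m-t)/C(n, m)` is attached in log space per sample size with
  log-sum-exp. The joint is built once per data set and cached per `m`,
  so scanning cluster sizes and testing many cells reuses it.
* **Compound Poisson (`cpe`)** — the parametric alternative: the case count
  in the sample is Poisson with rate `m·c/n` and each case draws its event
  count from `Q(y)`; evaluated by the Panjer recursion
  `P(x) = (λ/x) Σ_y y·Q(y)·P(x-y)`, extending the support until the
  truncated tail falls below a tolerance (default 1e-12, configurable).
  `c` may be non-integer, as when implied by an event rate.
* **Aggregate events (`ae`)** — with only `V` events known among `n`
  individuals, events are treated as indistinguishable and all
  `C(n+V-1, V)` arrangements as equally likely; the count in a sample of
  `m` has the occupancy mass
  `C(m+x-1, x)·C(n-m+V-x-1, V-x)/C(n+V-1, V)`. This discards the linkage of
  events to cases (a real information loss) but needs the least data.
* **Stratified variants** — sampling is conditioned within each stratum, so
  the per-stratum counts are independent and the total is the convolution
  of per-stratum `ee` (or `ae`) distributions evaluated at the per-stratum
  combined populations.

All binomial coefficients go through `gammaln`; sums of signed-magnitude
log terms use log-sum-exp. Exhaustive enumeration oracles (all subsets, all
occupancy arrangements) pin every family to 1e-10 on instances up to
`n = 12`, `V = 8`. At population scale (`n ~ 5·10^5`) `gammaln` itself
carries ~1e-9 absolute error in the exponent, so distribution-level
identities (normalization, means) are verified at 1e-8 there.

The formulation of the stratified multiple-hypergeometric support treats
the per-class bounds as `r_ys <= C_ys` (sampling can take at most the
class's members), matching the unstratified support; the `S = 1` reduction
is tested bit-for-bit.

## Choosing the cluster size and sequential testing

`k*_i(w)` is the smallest `k` with `P(X >= k) <= α` for the population of
cell `i` combined with its `w` nearest neighbours — equivalently the
100·(1-α) percentile of the null, rounded outward to the next integer. The
attained tail is the effective level `α*_i(w) <= α`; discreteness makes it
strictly smaller in general. Depths default to `w = 0, 1, 2`: combining
more than two neighbours merges large populations where a significant
excess is implausible, and the depth list is configurable per analysis.

Testing proceeds sequentially: test at `k*_i(0)`; if significant, stop
(then `L_i = w`); otherwise continue at the next depth, reporting the last
test when none is significant. Two consequences are inherent to the scheme
and deliberately not corrected: significant p-values sit close to α, and
multiple depths inflate the per-cell error beyond `α*` — which is why
overall significance is delegated to Monte Carlo rather than to any
per-cell correction.

When even the whole region holds fewer than `k*` events the statistic is
undefined; such cells are reported with `ell = I-1`, `p = 1`, not
significant (combining everything cannot be extreme).

## Monte Carlo assessment

Null data sets are generated by allocating each case class `C_y`
independently and multinomially across cells with probabilities `n_i/n`;
every draw conserves the class totals and hence the event total exactly.
The overall-clustering p-value is the proportion of simulated data sets
whose significant-cell count `R_α` is at least the observed one (plain
proportion, so 0 is attainable). Cluster-size plans depend only on
populations and region-wide marginals, both conserved under re-allocation,
so the plan is built once per analysis. For aggregate-only data the
re-allocation treats each event as a single-event case (events placed
independently); this is the natural sampling model when case linkage is
unknown, though it is not the occupancy null itself.

## Type I error harness

The harness mirrors the design of the false-cluster-rate study: constant
cell populations (68 cells by default), an event rate of 2 events per 1000
population, and five event-per-case scenarios S1–S5 with means 1.5, 1.07,
1.63, 1.25 and ~1.09. The scenario's implied case total `c = v/E[Q]` is
integerized by flooring `c·Q(y)` per class and repairing the event deficit
with single-event cases, which reproduces the fixed event totals (136, 680,
1088 at populations 1000, 5000, 8000). S5's printed probabilities sum to
0.999 and are renormalized (with a warning on manual construction).

Each cell is tested **once** per replication at its cell-alone cluster size
`k*_i(0)`; a cell rejects when the exact p-value at the realized statistic
is at most α. The compound Poisson null keeps the exact non-integer case
total for its rate (the model is rate-parametrized), while data generation
uses the integerized classes. Reported per method: the deterministic
effective level `α*` (identical across cells when populations are equal)
and the mean and SD across cells of each cell's empirical rejection
percentage over the replications; the mean and SD of the per-data-set
significant-cell count are also recorded. At 1000 replications and
`α* ≈ 2.5%` the binomial standard error implies an across-cell SD near 0.5
percentage points, which the harness reproduces.

When no explicit geometry is supplied the harness places cells on a line at
unit spacing. With equal populations the cells are exchangeable, so the
geometry fixes only which cells merge, not any null distribution; with
unequal populations a real neighbour ordering should be supplied.

## Synthetic data: what it does and does not emulate

The generator reproduces the study conditions of the simulation design —
fixed regional event totals, multinomial allocation proportional to
population, scenario-driven event-per-case mixes — and the packaged
synthetic end-to-end fixture adds irregular populations and centroid
geometry. It does not emulate spatial correlation of risk, covariate
structure, population drift over the study window, or reporting artefacts
in administrative data; passing tests demonstrate correctness of the
probability machinery and calibration under the stated null, not
robustness of cluster findings in any particular surveillance system.

## Numerical and design choices

* Distances: haversine on latitude/longitude, Euclidean on planar
  coordinates (the cells file schema declares which); a supplied distance
  matrix or explicit neighbour ordering overrides computation. Distance
  ties break by ascending cell identifier, making orderings deterministic
  and permutation-equivariant.
* Zero-population cells are legal, retained in orderings, and mergeable.
* Tail probabilities sum the shorter side of the pmf; `k = 0` gives 1,
  `k > support` gives 0.
* Cluster-size scans start at the null mean and walk to the smallest
  qualifying `k`, with results cached by combined population, so constant-
  population regions pay for one scan.
* Reproducibility: one root seed drives a single `numpy` Generator;
  identical seeds give byte-identical CLI outputs.
* The exact-event joint weight stays within float range for case totals up
  to roughly 2400 (`2^-c` underflow bound); beyond that the implementation
  would need per-class rescaling, which is out of scope at administrative
  scales.

## Known limitations

* Power against planted clusters is not studied here; the harness measures
  Type I error only.
* The `hc` and `cpe` analyses have no stratified variant (requesting one
  raises an error); stratification is supported for `ee` and `ae`.
* Per-cell p-values from the sequential scheme are not adjusted for
  multiplicity across depths or cells; interpret cell-level flags jointly
  with the Monte Carlo overall p-value.
* The occupancy null's "all arrangements equally likely" assumption implies
  heavier-tailed per-person event counts than most real data; AE flags are
  conservative or anticonservative depending on the true event-per-case
  mix.
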