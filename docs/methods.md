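# Methods

This note documents the models implemented in `latentmut`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely open.

## Models

### Constant size (`latentmut.ewens`)

The equilibrium Wright–Fisher diffusion with K-allele parent-independent
mutation gives the sampling probability of allele counts as a ratio of rising
factorials of θπᵢ. Expanding a rising factorial in unsigned Stirling numbers
of the first kind introduces the latent mutation number kᵢ for each allele;
conditional on the counts, each kᵢ follows the Ewens number-of-alleles
distribution with parameter θπᵢ, independently across alleles. The module
evaluates:

* the exact two-allele and K-allele sampling probabilities (ordered and
  unordered);
* the latent-mutation pmf `P(k₁|n₁)`;
* the leading large-n term of the two-allele pmf, whose ratio to the exact
  value tends to one;
* the "augmented" root-conditioned model: condition on all r lineages being
  the common type at the first time there were r of them, then apply the
  independent-Poissons description to the rest of the genealogy. Its limiting
  error relative to the exact diffusion result is
  Γ(θ+r)/Γ(θπ₂+r) · exp(−θπ₁(H_{r−1} − γ)) = 1 + (2−π₁)π₁/2 · ψ′(r) θ² + O(θ³),
  where ψ′ is the trigamma function. Because ψ′(2)/ψ′(1) ≈ 0.392, taking
  r = 2 instead of r = 1 removes about 60% of the small-θ error.

Conventions: n₁ = 0 is a point mass at k₁ = 0 throughout (no copies, no
latent mutations).

### Independent Poissons (`latentmut.poisson_model`)

For a rare variant in a very large sample on any genealogy with finite
expected height, the latent-mutation counts a₁, a₂, … by descendant class are
independent Poissons with means (θ₁/2)τ̄ᵢ. The joint law of
(n₁, k₁) = (Σ i aᵢ, Σ aᵢ) factorizes into a Poisson mutation number (mean =
mutrate) and, given k₁, a k₁-fold convolution of the relative branch-length
weights. The composition sum is evaluated by iterated discrete convolution
(O(b²) per k₁) rather than enumerating ordered compositions (exponential);
the enumeration is retained as a test oracle. This makes b in the hundreds
feasible, though the working defaults are the practical limits b = 40 and
kmax = 7: at 3 expected mutations per site the mass beyond k₁ = 7 is ≈ 1.2%,
and mutrates much above 3 are outside the model's intended range. All
truncated probability (k₁ > kmax, counts beyond b, branch classes beyond the
stored prefix) is accumulated into an explicit `truncation_mass`, never
silently dropped.

Only the *total* Σᵢ τ̄ᵢ enters beyond the stored prefix, so a spectrum can be
supplied as a b-length prefix plus a total — or as relative weights plus an
independently estimated mutrate. With τ̄ᵢ = 2/i the joint pmf reduces exactly
(to 1e−10 in log space, verified) to the Stirling-number closed form, and the
posterior of k₁ given n₁ coincides with the Ewens law of the constant-size
theory. For large n₁ the posterior of k₁ − 1 approaches a Poisson with mean
mutrate (shifted-Poisson limit), provided as a reference distribution.

The Poisson rates (θ₁/2)τ̄ᵢ can be read as arbitrary nonnegative production
rates λᵢ; nothing downstream assumes they came from a genealogy.

### Branch lengths and growth (`latentmut.growth`)

`tau_from_intervals` maps expected coalescent intervals E[T_k] to the
spectrum via E[τᵢ] = Σ_k k E[T_k] C(n−i−1, k−2)/C(n−1, k−1) (exchangeable
topology), computed with log-gamma binomial ratios. Two conservation laws are
exact combinatorial identities and are property-tested at n up to 2000:
Σᵢ τ̄ᵢ = Σ_k k E[T_k] and Σᵢ i τ̄ᵢ = n Σ_k E[T_k].

For exponential growth (β = N₀r on the coalescent scale of N₀ generations)
the cumulative lineage-decay curve f(x) = (1/β)log((2β/n)(1−x)/x + 1) at
x = k/n yields the interval approximation E[T_k] = 2/(k(2β(1−k/n)+k)). The
displayed source form of this expression is typographically ambiguous; the
implemented reading is fixed by three independent checks: the β → 0
constant-size limit, finite differences of f, and the fast-growth limit
1/(βk(1−k/n)). Carrying the same continuum approximation through the
branch-length sum gives

    E[τᵢ] = (n/β) / (i(i+1)) · ₂F₁(1, 2; i+2; 1 − n/(2β)).

Numerical evaluation: scipy's ₂F₁ is accurate for β/n ≳ 0.6; below that the
argument is far outside the unit disk and the equivalent integral
(n/β)∫₀¹ x(1−x)^{i−1}/(1−(1−n/(2β))x) dx is evaluated by adaptive quadrature
(rel. tol. 1e−8, split at x = 0.5 to tame the endpoint factor). The two
routes agree to 1e−6 relative where both apply, and any non-finite
hypergeometric result falls back to quadrature. The star-tree limits
((log(2β/n)−1)/(β/n) for i = 1, 1/(i(i−1)β/n) for i ≥ 2) are approached with
relative error ~ log(β/n)/(β/n).

`intervals_growth` is a large-n approximation and warns below n = 1000.
`growth_calibration` packages β = N₀r; with N₀ = 5×10⁷, r = 0.0064 per
generation and 30-year generations, β = 3.2×10⁵. Reported historical sizes
use N(t) = N₀e^{−βt} with t in units of N₀ generations; published
illustrations of this demography quote historical sizes that we could not
reproduce under this (stated) time-scale convention, so `size_years_ago`
simply reports the convention's value.

### Conditional ancestry simulator (`latentmut.ancestry`)

The conditional ancestral process follows lineages back to their first
mutation: each event picks allele i with probability nᵢ/n, is a mutation with
probability θπᵢ/(θπᵢ + nᵢ − 1) and a coalescence otherwise, and decrements
nᵢ. Because the interleaving of alleles does not affect the counts, the exact
simulator draws each allele's Bernoulli chain independently (vectorized over
repetitions, one seeded substream per allele); a `trace_realization` variant
produces a single fully ordered event list.

The large-n variant simulates the three-jump process for one rare allele
against nK common lineages: rare mutation (which converts the lineage to the
common type), rare coalescence, and common-lineage decrement. Empty mutations
(common type to itself) are excluded by construction, as they vanish in the
large-n limit; the exact variant counts all first mutations, and the two
agree on k₁ within Monte-Carlo error once nK ≫ n₁. The number of common
decrements between rare events is sampled exactly by inverting its survival
function (a falling-factorial ratio, evaluated with log-gamma and a
vectorized binary search), which avoids simulating the O(nK) common events
individually. Waiting times use one exponential draw per common-lineage level
at instantaneous total rate m²/2, drawn in bounded-memory chunks; the rare
events' own O(n₁) waits are included, the O(1) rate perturbations from
mutation re-insertions are not.

Closed forms: E[T₁] ≈ 2log(n₂)/n₂ for a singleton (heavy-tailed: the
sample mean converges slowly, so tests compare the conditional-mean average
given the sampled lineage counts) and 2/(n₂(n₁−1)) otherwise; the expected
common lineages remaining at the i-th rare event is n₂(n₁−i+1)/(n₁+1). The
source display of the latter is ambiguous; this reading is fixed by matching
all three of its printed numerical anchors (≈2780, >1200, >400). Note these
closed forms count n₂ lineages at the start of the rare allele's ancestry;
tests exercise them at i = 1 and i = n₁ where the reading is unambiguous.

### Binned-SFS pipeline (`latentmut.pipeline`)

Inputs are per-bin tables (L total sites; S₀ monomorphic; S₁..S_b sites with
a rare variant in i copies; counts above b stay inside L as an unmodeled
remainder). Each rare variant at a site is an independent record, so
multi-allelic sites contribute one record per rare variant. The fit is
deliberately empirical — no demographic model:

1. mutrate per bin: −log(S₀/L), the inverted Poisson zero class. Delta-method
   s.e. sqrt((e^m − 1)/L). A fully monomorphic bin gets rate 0 with a flag;
   a bin with no monomorphic sites is an error (rate unidentifiable).
2. relative branch lengths: pooled Sᵢ/(L−S₀) over designated low-rate bins,
   where single mutations dominate. The default pool accumulates the
   smallest-mutrate bins until ≥ 1e5 polymorphic sites (configurable); the
   estimator deliberately ignores multi-mutation contamination, which is
   second-order at pool rates ~ 0.01–0.04.
3. expected counts E[Sᵢ] = L Σ_k Poisson(k; mutrate) · P(n₁ = i | k), with
   cells below E[Sᵢ] < 1 merged into a single tail cell (observed counts
   merged identically). Bins with fewer than `min_polymorphic` (default 100)
   polymorphic sites are excluded from fit outputs.
4. diagnostics: posterior P(k|i) tables with the shifted-Poisson reference,
   and an infinite-sites comparison whose linear prediction L·mutrate·τ̄ᵢ/Στ̄
   is flagged when it exceeds L (the infinite-sites model predicting more
   singletons than sites). No goodness-of-fit p-values are emitted; residual
   tables support visual assessment.

The sample size n enters nothing beyond metadata, since only relative branch
lengths and per-site mutrates are fitted; datasets whose n varies by a few
percent across bins are treated as having a single nominal n.

## Synthetic data (`latentmut.simulate`)

The generator draws, per site, independent Poisson counts aᵢ with means
mutrate·rel_tauᵢ for i = 1..b plus one lumped rate for all branch classes
above b, and aggregates Σ i aᵢ into the binned tables. It samples the model's
assumptions *exactly* — never trees — so pipeline tests on generated data
isolate pipeline defects rather than model misspecification. Consequently
passing tests demonstrate correct inference *under the model*; they say
nothing about features of real data the model excludes: nested mutations at
moderate sample sizes, linkage between sites, variance inflation from
genealogy sharing, sequencing error, or rate misclassification across bins.
True per-site mutation numbers are available as an explicitly non-observable
side channel for oracle tests. Poisson draws are untruncated; `kmax_sim`
(≥ 12 > kmax) only caps the truth-table width, keeping truncation effects
visible to tests.

Default study conditions used by the end-to-end tests: 97 bins (or 30 in the
faster unit test) with mutrates log-spaced over [0.01, 2.5] — matching the
observed range at human synonymous sites — and geometrically decaying bin
sizes so most sites sit in low-rate bins; relative branch lengths either
constant-size (2/i normalized by the full-tree total at n = 1e5) or
exponential-growth with β/n = 3, the value that reproduces the observed
singleton/doubleton ratio at low-rate human sites. Total simulated sites are
kept near 2×10⁶ so the default suite runs in well under two minutes.

## Tolerances and determinism

* pmf normalization: 1e−12 (log-sum-exp); Stirling numbers exact big
  integers with a cached log table (float conversion via bit-length to avoid
  overflow beyond 1e308).
* All rising factorials and binomial ratios via log-gamma differences
  (needed up to n = 10⁶ in asymptotic checks).
* joint-pmf mass accounting: 1e−10; dual-route ₂F₁/quadrature agreement:
  1e−6 relative; conservation laws: 1e−10 relative.
* Monte-Carlo tests use fixed seeds, compare only cells with expected count
  ≥ 10 at 3 standard errors, and Rao-Blackwellize heavy-tailed time
  summaries.
* Every simulator takes a single seed; substreams are spawned
  deterministically, and identical configuration reproduces identical
  output bit-for-bit.

## Known limitations

* The large-n results assume the rare count stays small relative to the
  sample; no finite-n correction is attempted beyond the augmented root
  model.
* The growth formulas are continuum approximations, least accurate for the
  deepest coalescent intervals (small k) and for n below ~10³.
* The pipeline's shared-branch-length assumption (one relative spectrum for
  all bins) is inherited from the empirical method it implements; violations
  (e.g. rate-correlated selection) would bias high-rate-bin expectations.
* No nested-mutation corrections and no selection; the rate hook λᵢ exists
  but no selection-aware rates are provided.
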