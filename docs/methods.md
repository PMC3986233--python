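# Methods

`dynapop` builds small-area synthetic populations with a two-fold nested
structure (individuals within households within areas), evolves them with an
age-structured two-sex demographic model, and attaches percentile-bootstrap
prediction intervals to the evolved characteristics. This note records the
models, the conventions the implementation fixes where the design was open,
and what the synthetic study conditions do and do not demonstrate.

## Baseline synthesis by combinatorial optimisation

An area's population is a multiset of households drawn from a seed microdata
pool (the stand-in for a 1% census sample file). A candidate sample X is
scored against the area's marginal tables with the quadratic fitness

    F(X) = Σ_k (θ̂_k(X) − E[θ̂_k])² / Var(θ̂_k),

with one estimator θ̂_k per marginal cell: person counts per (sex, age band)
and household counts per household type. Individual-level cells are always
recomputed from household members, so the nesting is preserved by
construction. The search swaps a uniformly chosen selected household against
a uniformly chosen pool household and accepts strictly improving swaps
(pure hill climbing; the accepted-fitness trace is strictly decreasing
within a restart). Equal-fitness swaps are rejected. Optional simulated
annealing accepts a worsening swap with probability exp(−ΔF/T), T ← cT per
iteration (defaults T₀ = 1, c = 0.995). Search stops at F ≤ ε (default
10⁻⁹) or after `patience` (default 500) iterations without improvement,
restarting up to `n_restarts` (default 5) times; exhausting the budget
returns the best sample found with a warning flag rather than raising.

Conventions and their reasons:

- **Swap unit = whole households.** Swapping individuals would break
  household-type invariants; household swaps move members together.
- **Replication.** A household may be selected more than once (fresh ids
  are issued): a small pool must be cloneable to cover a larger area. The
  pool must still contain at least `target_M` households (widening with a
  surrounding area's pool is supported); this mirrors how an undersized
  local pool is handled in practice.
- **Variances.** Var(θ̂_k) is estimated from the pool as M·s²_k (s²_k the
  pool variance of per-household contributions to cell k, M the target
  household count), floored at v_min = 0.5 so exactly-constant cells cannot
  produce a division by zero.
- **Reconciliation.** Released census tables are independently perturbed,
  so the person total implied by age×sex may disagree with the household
  table (household counts × mean persons per household of that type,
  estimated from the pool). The consensus total is the mean of the two
  implied totals (rounded half-to-even); age×sex cells are re-apportioned
  to that total by largest-remainder rounding, which moves cells in one
  direction only and hence minimises the total absolute adjustment.
  Exactly-consistent (unperturbed) tables are used verbatim.
- **Perturbation model for fixtures.** Integer noise uniform on
  {−p, …, +p} per cell (default p = 2), truncated at 0 — a minimal model
  of agency-applied small random adjustments, which have no published
  distribution.

The exhaustive-search check enumerates every multiset of the pool (the
search's own space) on instances small enough to enumerate; the best subset
without replication is implied as an upper bound.

## Two-sex dynamics

The aggregate state carries female/male counts by single year of age
(maximum age w = 100: everyone dies before reaching w), a couples matrix
C[i,j] (wife age i, husband age j) and widow/widower stocks. One annual
step applies, in order: (1) events from the start-of-period state — new
couples N (below), divorces D = C∘ν, births B = Σ C_ij b_ij split 105:100
male:female; (2) couples C' = (C + N − D)·s_f s_m; (3) widows
W' = (W + Σ_j C_ij d^m_j − widow remarriages)·s_f and symmetrically for
widowers; (4) totals grow by (1 + R), R = immigration − emigration −
death; (5) ageing shifts every age index, births enter age 0, and age
w−1 exits (a spouse ageing out leaves a widow/widower).

The published recursions are simultaneous; realising them in this order
reproduces each recursion exactly while giving the micro-simulation an
unambiguous event schedule. Three conventions make the deterministic step
the *exact expectation* of the micro step, which is what the replicate-mean
agreement experiment verifies:

- births are drawn per start-of-period couple, regardless of a divorce or
  death later in the same period, and newborns face no mortality in their
  birth period;
- a person whose start-of-period spouse dies becomes widowed even if the
  couple divorced within that period; a spouse of a within-period couple
  who loses the new partner reverts to single;
- the widow/widower recursions subtract remarriages (widowed persons are
  eligible at the remarriage rate μ⁽²⁾); with μ⁽²⁾ = 0 this reduces to the
  classical inflow-only recursion.

**Couple matching.** The pairing function for new couples is not pinned
down by two-sex theory (the classic consistency problem); the package uses
harmonic-mean matching, N_ij = μ_ij · 2 S^f_i S^m_j / (S^f_i + S^m_j),
rescaled proportionally so no row/column total exceeds the available
singles. It is symmetric in the sexes, vanishes when either side is empty,
and reduces to μ·S when the sides are balanced. First marriages draw from
the never-married/divorced pool, remarriages from the widowed pool.

**Micro realisation of marriages.** Per female age, the number of brides
is floor + Bernoulli of Σ_j N_ij (never exceeding the singles available,
since the matching caps row totals); each bride samples a husband age from
her row of N, falling back to the nearest age with an available single
male. This keeps the female marginal expectation exact and the husband-age
distribution exact up to rare exhaustion events.

Other rate conventions: banded rates are constant within their band (step
functions); annual probabilities convert to per-period ones as
q = 1 − (1−p)^(1/n) when a year is split into n periods (default n = 1);
negative intermediate masses (possible under extreme rates) are clamped to
zero and logged, never silently. Birth rates are female-age-indexed
(b_ij := b_i) because the published table only resolves the mother's age.
Emigration acts at the individual level inside R; end-of-year immigrants
are whole households cloned uniformly from the current population, which
reproduces its empirical joint distribution of household type, ages and
sexes.

## Household-type transitions

A household state is (female-adult band, male-adult band, ≤ 2 tracked
children with sex and band); the five census types are derived from that
composition, with an explicit absorbing `extinct` state. Ten event
components act within a period (deaths of the four member classes, first
marriage, remarriage, birth, divorce, daughter/son leaves home). An
outcome is a full 0/1 vector δ over the components; under independence its
probability is Π_{δ_c=1} π_c · Π_{δ_c=0} (1 − π_c). The transition
probability g₁ → g₂ sums this over the outcome vectors mapping g₁ to g₂.
Full outcomes are mutually exclusive, so the inclusion–exclusion union
formula collapses to a plain sum; the general union form over partially
specified cases is implemented separately and agrees on disjoint inputs.

Outcome application is total: an event inapplicable at its turn (birth in
a lone-person household) is a no-op, and its component probability is
built as zero from the rates, so the 2^10 outcomes always partition the
probability mass and rows sum to one by construction. Compound outcomes
are real transitions: a couple-only household can reach one-parent in a
single period via birth + death of one adult. Conventions: events apply in
the order marriage → birth → divorce → deaths → leaving home; birth and
divorce require a couple at the *start* of the period; a marriage adds a
same-band opposite-sex partner; on divorce the male adult leaves (children
stay) and his new household is not tracked by the row; a newborn is
recorded as a girl in the aggregated state (a single birth component
cannot split destinations by sex — the micro-simulation draws newborn sex
properly, and household-type-level quantities are unaffected); child
components act on the oldest tracked child of the relevant sex, so a
second same-sex child's mortality is not represented in a row. Component
probabilities are looked up at band midpoints, which is exact for
constant-within-band rates.

## Bootstrap prediction intervals

Uncertainty in evolved characteristics is quantified by replicating the
whole simulation from resampled baselines: each of B replicates draws
households with replacement (resampling whole households keeps the nesting
intact) up to the original household count, evolves forward with an
independent RNG stream, and records area-level characteristics. The
interval is the percentile method on order statistics ⌈B·α/2⌉ and
⌈B·(1−α/2)⌉ — endpoints are always elements of the replicate set — and the
bootstrap SE is the replicate standard deviation. B defaults to 1000;
validation experiments use B = 200 for speed. Per-replicate streams are
spawned from the root seed with `SeedSequence.spawn`, so enlarging B never
perturbs earlier replicates. By default replicates re-run the evolution
only; re-running baseline synthesis per replicate is left to the caller
(resample the upstream pool and synthesize per replicate).

## Validation metrics

Relative bias RB = 100·(estimate − actual)/actual per (area,
characteristic); MRB is the median of defined RBs per characteristic
across areas (mean of the central two for even counts). Zero-actual cells
have no RB and are reported separately, never dropped silently — small
areas otherwise vanish from exactly the comparisons where they are least
reliable.

## Synthetic study conditions

Real seed microdata and census tables for this problem are proprietary, so
the fixture generator emulates their structure: a ground-truth region with
a configurable household-type mixture (defaults roughly matching an
Australian urban area: 26% couple-only, 30% couple-with-children, 24%
lone-person, 11% one-parent, 9% other-family), piecewise-uniform adult and
child age distributions, spousal age gaps triangular on [−5, +10] years
(male minus female), 1–3 children per family household, a
household-preserving 1% simple random sample as the seed pool, and
perturbed or exact marginal tables. Birth and death rates are the
published state-level tables (births per 1000 females by age band; deaths
per 10000 by sex and age band). The males-65+ death rate is carried
verbatim even though its magnitude (0.896/yr) is demographically
implausible — likely a denominator inconsistency in the source table — and
a `rate_scale` option lets users rescale it explicitly; nothing is
corrected silently. Marriage, remarriage, divorce and leaving-home rates
were published only graphically, so the fixture carries zeros and a
separate synthetic rate set provides plausible magnitudes (first marriage
peaking at 0.08/yr for single women in their late twenties, divorce at
1–2%/yr per couple, leaving home at 12–25%/yr for dependants over 15).

What passing the experiments shows — and does not. The generator draws
household members independently within simple parametric distributions; it
has no spatial autocorrelation, no socio-economic attributes, no
non-private dwellings, and areas are exchangeable draws from one mixture.
Recovery experiments therefore demonstrate the *machinery* (search
optimality, exact-expectation dynamics, interval calibration) under the
homogeneity assumption, not performance on real census geographies, where
between-area heterogeneity and table perturbation interact. Problem sizes
were chosen to keep the full validation suite comfortably runnable on a
single CPU: 20 areas of ~380 households against a ~1,000-person pool for
the region experiment, 500 replicates for the micro/deterministic
comparison (cells aggregated to 5-year bands, 10-year band pairs for
couples, so Monte-Carlo standard errors are meaningful), and 200 outer
replications × B = 200 for interval coverage, with the coverage experiment
run in deterministic mode where the fixture-rate projection is linear in
the baseline and the scaled full-region projection is therefore the exact
expected prediction.

## Known limitations

- The aggregate model tracks marital structure (couples matrix, widow
  stocks) but not divorced-vs-never-married status; divorced persons
  re-enter the first-marriage pool.
- Emigration of a married person dissolves the couple without widowhood in
  the micro model; the aggregate model applies migration only to totals.
- The household-transition matrix does not see events initiated by members
  a row does not track (a new spouse's death within the joining period,
  the younger of two same-sex children).
- Time-varying vital rates, social networks, agent learning, multi-family
  dwellings, same-sex couple formation and between-area migration are out
  of scope.
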