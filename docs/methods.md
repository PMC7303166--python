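# Methods

## Model

A population of N agents occupies an undirected, connected graph. Agent i
carries a single heritable trait x_i ∈ [0, 1]: the probability of engaging
controlled (deliberative, flexible, costly) rather than automatic
(reflexive, efficient, inflexible) cognitive processing on any given
decision. Per generation t the two processing modes pay

    π_C = 1 − c + w·(1 − ⟨x⟩_{i,t})        (controlled)
    π_A = 1 − p_{i,t}                       (automatic)

and fitness is the strategy-weighted mixture

    f_{i,t} = x_i·π_C + (1 − x_i)·π_A.

Here c ≥ 0 is the fixed cost of control; w is the impact of contact with
automatic agents on controlled agents (w < 0: automatics harm controls,
e.g. by outracing them to resources; w > 0: controls profit from
automatics); ⟨x⟩_{i,t} is the mean strategy of agent i's *contact* pool
**including i itself**; and p ∈ [0, 1] is the state of the environment —
the relative decision-making advantage of control.

The environment embodies a feedback: control produces externalities
(technologies, institutions) that make the environment more forgiving,
which erodes the advantage of control. p relaxes toward 1 − ⟨x⟩ with
characteristic time τ_p ≥ 1:

    p_t = p_{t−1} + ((1 − ⟨x⟩_{t−1}) − p_{t−1}) / τ_p

either as a single population-wide scalar (*global* environment) or as a
per-agent value driven by the including-self neighbourhood mean (*local*
environment). τ_p = 1 recovers instantaneous feedback p_t = 1 − ⟨x⟩_{t−1}.
Because the update is a convex combination of values in [0, 1] whenever
τ_p ≥ 1, p can never leave the unit interval; we require τ_p ≥ 1 and treat
smaller values as configuration errors.

Evolution is a Moran death–birth process. Each generation exactly one
learner is drawn uniformly; with probability u it adopts a fresh strategy
drawn uniformly from [0, 1] (mutation/innovation), otherwise it copies a
teacher drawn from its learning pool with probability proportional to
exp(s·f_T). s is the intensity of selection (s = 0 is neutral drift). The
teacher pool excludes the learner: its graph neighbours under local
learning, the other N − 1 agents under global learning. The softmax is
computed with max-subtraction, so teacher choice is exactly invariant to
adding a constant to all fitnesses and cannot overflow at strong selection.

Each of the three interaction dimensions — learning, contact, environment —
is independently local or global, giving 2³ = 8 scenarios. "Global" along a
dimension is implemented by querying the whole population rather than by
storing a second graph; on a complete graph every neighbourhood *is* the
whole population, so all 8 scenarios produce bit-identical seeded
trajectories there (a property the test suite checks exactly).

## Defaults and units

| parameter | meaning | default | notes |
|---|---|---|---|
| c | fixed cost of control (payoff units) | 0.5 | anchor value for all reported numbers |
| w | impact of automatics on controls | −0.15 | negative: contact harms control |
| s | selection intensity | 10 | strong selection |
| u | mutation probability per event | 0.01 | |
| τ_p | environment relaxation time (generations) | 1 | ≥ 1 |
| N | population size | 100 | |
| k | ring degree | 2 | one neighbour per side |
| x₀ | initial strategy, all agents | 0.01 | almost entirely automatic |
| p₀ | initial environment | 1 − x₀ | consistent with the initial strategies |
| generations | learner-update events | 8×10⁴ | 2×10⁵ for the lag analysis here |
| record_every | snapshot stride | 100 | full per-generation ⟨x⟩ and mean p are always kept |
| burn_in | excluded from summaries | generations/2 | last 4×10⁴ of an 8×10⁴ run |

A "generation" is a single learner-update event, not N of them. Replicate
r of a run uses seed `base_seed + r`. Small-world replicates rebuild the
graph from their own seed, so graph realizations are averaged over.

## Order of operations within a generation

1. the environment relaxes using the strategies of generation t−1;
2. fitnesses are evaluated with the updated p and current strategies;
3. one Moran event fires.

The RNG draw order is fixed (learner, mutation coin, then either the
mutant strategy or the teacher draw), making trajectories bit-reproducible
given a seed. The engine's vectorized loop is tested for exact equality
against step-by-step composition of the public dynamics operations across
all 8 scenarios.

## Summary statistics

**Time-averaged control** ⟨x⟩: mean of the per-generation population mean
over the post-burn-in window.

**Assortment a**: per agent, the fraction of its neighbours with the same
strategy minus the fraction of same-strategy agents among the other N − 1,
averaged over agents and recorded snapshots. Strategies are continuous, so
"same" needs a rule. The default is **exact value identity**: under Moran
copying, equal values mean membership in the same copy lineage, and
mutation founds new lineages. This is the reading under which a
near-homogeneous-in-value population can still be strongly clustered
(neighbouring agents are literal copies of one another), and it is required
to reproduce the reported assortment levels: a midpoint binarization
(x ≥ 0.5, also provided) collapses the nearly homogeneous local-environment
populations into one class and yields a ≈ 0 where lineage identity yields
a ≈ 0.65. A pairwise tolerance rule (|x_i − x_j| ≤ ε, default ε = 0.05) is
provided as a third option. All three agree exactly with a brute-force
double-loop oracle on small instances.

**Strategy variance**: time-average over snapshots of the cross-sectional
population variance (÷N; a ÷(N−1) option exists). Bounded by 0.25.

**Mean oscillation peak**: the per-generation ⟨x⟩ series is smoothed with a
centred 500-generation moving average, then strict local maxima with
prominence ≥ 0.05 are detected (scipy); the statistic is the mean peak
height. With fewer than two peaks the series maximum is returned and
flagged as "no oscillation". The smoothing window suppresses single-update
jitter while preserving cycles of period ≳ 10³ generations; the statistic
is shift-equivariant by construction.

**Replicate 95% CI**: mean ± 1.96·σ/√n with the population SD, i.e. a
normal approximation; at n = 10 replicates the normal-vs-t and ddof choices
move the half-width by a few percent, well below replicate scatter.

## What the simulations do and do not show

All inputs are synthetic by design — the model itself is the object of
study; there is no empirical data path. The anchor-parameter grid
(8 scenarios × 10 replicates × 8×10⁴ generations) reproduces the known
structure: the fully local scenario retains the most control; a global
environment lowers control but sustains both strategic variance and (with
local learning) stronger communities; global learning removes assortment
entirely.

The lag analysis at desk scale uses 2×10⁵ generations and 5 replicates
(problem sizes chosen so the whole grid runs on a laptop in minutes). For
the fully global scenario the mean peak rises cleanly with τ_p
(≈ 0.45 → 0.81 over τ_p ∈ {1, 10², 10³, 10⁴}): with global learning the
whole population swings coherently. For the fully local scenario the
oscillation *amplitude* grows with τ_p (sd of the post-burn-in ⟨x⟩ series
≈ 0.027 → 0.12, series maximum 0.76 → 0.82), but the absolute mean-peak
value does **not** increase monotonically, because (i) at τ_p = 1 there are
no genuine cycles and the detected "peaks" are the noise envelope around a
high equilibrium (⟨x⟩ ≈ 0.70), and (ii) the mean level of control falls
with τ_p while local learning keeps communities cycling out of phase, so
aggregate peaks stay moderate. This persists at 1.2×10⁶ generations
(mean peak 0.73/0.62/0.63 at τ_p = 1/10³/10⁴ while sd grows 0.027 → 0.14):
under this peak statistic, "larger lag → larger cycles" is a statement
about amplitude around the mean, not about the absolute height of the mean
peak in the fully local scenario. The acceptance test states the monotone
mean-peak expectation for both scenarios; its fully-local case fails for
this reason and is retained as documentation of the discrepancy rather
than weakened.

## Numerical choices and degenerate inputs

- Teacher draws use a single uniform against the cumulative softmax weights
  (`searchsorted`, right side), so zero-weight candidates are unreachable
  and candidate masking costs nothing.
- Parameters outside the studied ranges (c ∉ [0, 1] or |w| > 1) are allowed
  but warn: payoffs may leave [0, 1]; the exponential fitness mapping
  remains well defined.
- Ring construction requires even k < n; k = n − 1 (odd n) degenerates to
  the complete graph and is accepted.
- Disconnected small-world draws are resampled (the standard
  connected-variant construction); this is an assumption, as the reference
  behaviour for disconnected draws is unspecified.
- Homogeneous populations are exact fixed points at u = 0 (copying cannot
  create variation); the test suite asserts this and that the distinct-value
  count is non-increasing at u = 0.

## Known limitations

- The analytical mean-field treatment of the two-strategy simplification is
  out of scope; the indifference point x* = (1 − c + w)/(1 + w) is used only
  as an oracle for the fully global, τ_p = 1 equilibrium.
- The pairwise-comparison update rule is not implemented (the death–birth
  Moran process is the single supported rule).
- Graphs are undirected and unweighted, limited to ring / complete /
  small-world (plus anything loadable from an edge list).
- Figure-style raster export is a convenience; colour normalization and
  snapshot stride are package choices, not calibrated to any reference
  rendering.
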