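# Model and methods

`moodsim` simulates a society of agents with and without mood disorders
playing an iterated Continuous Prisoner's Dilemma (CPD) on a static
social network, to compare cumulative payoffs across agent types and
memory regimes.  This note records the model, its parameters, the design
choices made where the design was genuinely open, and what the package's
experiments do and do not show.

## Agents and types

Each agent has a trait reward sensitivity β⁰ that defines its type:

| type      | β⁰            | initial mood ν⁰     | mood rate κ | drive ζ      | target degree η |
|-----------|---------------|---------------------|-------------|--------------|-----------------|
| rational  | exactly 1     | 0                   | 0           | 0.5          | 0.5·n           |
| manic     | U(1, 10]      | (β⁰−1)/(β_max−1)    | 0.1         | (0.5, 1]     | [0.5·n, n−1]    |
| depressed | U[0, 1)       | β⁰−1                | 0.1         | [0, 0.5)     | [0, 0.5·n]      |
| bipolar   | derived       | clamp(sin ωt + λ)   | —           | from β⁰(t=0) | from β⁰(t=0)    |

Drive (the per-round participation probability) and target degree (the
size of the personal network) are min–max rescalings of β⁰ around the
rational anchor 0.5: mania raises engagement and social reach, anhedonia
lowers both.  β_max = 10 throughout.  The manic initial-mood expression
divides by (β_max − 1) so that manic moods start in (0, 1]; the
alternative of adding 1 to that ratio would place them in [1, 2], outside
the mood domain.

Bipolar agents carry an intrinsic mood rhythm ν(t) = clamp(sin(ω·t) + λ,
−1, 1) with offset λ ~ U[−1, 1] (mostly-manic if positive) and angular
rate ω redrawn every 50 rounds from Exponential(mean ω′), ω′ ~ U[0.01,
0.5] rad/round (cycle periods of roughly 12–600 rounds inside a
2000-round run).  Their reward sensitivity is re-derived from mood each
round: β = ν + 1 for ν < 0 and β = 1 + ν(β_max − 1) for ν > 0, continuous
and equal to 1 at neutral mood.  The clamp keeps ν inside the domain on
which this map and the retrieval kernel are defined.

## One interaction

When active neighbors A and B are paired at round t:

1. Both retrieve their traces about the other (below) and form the
   expectation E = mean cooperation over the retrieved set, or a
   cold-start expectation if nothing was retrieved.
2. Both cooperate at their expectation, c = E (simultaneous moves from
   pre-round state).
3. Payoffs bilinearly interpolate the PD matrix:
   p_A = c_A c_B C + c_A(1−c_B) S + (1−c_A) c_B T + (1−c_A)(1−c_B) D,
   with defaults (C, T, D, S) = (4, 5, 1, 0) satisfying T > C > D > S and
   2C > T + D.  The classic (5, 3, 1, 0) violates the second condition
   and is rejected at config load.
4. Emotion is appraised as δ = tanh(β c_B − c_A): the perceived reward
   (the counterpart's cooperation scaled by the agent's current reward
   sensitivity) minus the expectation, squashed to (−1, 1).  One code
   path serves all types; at β = 1 the pre-squash argument is the plain
   reward-minus-expectation difference.
5. Each agent encodes a trace about the other (below).
6. Non-bipolar agents update mood by ν ← tanh(ν + κ(δ − ν)); bipolar
   mood follows the rhythm on the global round clock and ignores κ.

Unmatched or inactive agents receive no payoff and no updates that round
(mood does not decay in idle rounds; no rule for that is part of the
model).

## Memory

A trace stores the counterpart, the remembered reward, the emotion at
encoding, and a decaying strength.

**Encoding.**  Initial strength is V-shaped in emotion:
φ₀ = −k_N·δ + c for δ ≤ 0 and k_P·δ + c for δ > 0, with defaults
k_N = k_P = 80 and intercept c = 10, so φ₀ ∈ [10, 90] < 100.  The bias
presets are (k_P, k_N) = (80, 40) (positively biased, ξ = k_P/k_N = 2)
and (40, 80) (ξ = 0.5).

**Forgetting.**  Strength decays as φ(t) = φ₀ e^(−θ·elapsed), measured
from the last encoding *or* refresh; a trace whose strength falls below
φ_min = 1 is deleted permanently.  The unrefreshed lifetime is therefore
ln(φ₀/φ_min)/θ.  A successful retrieval resets strength to φ₀
(re-anchoring the decay clock is the only reading consistent with
exponential decay from φ₀).

**Retrieval.**  A query about counterpart B filters to B's traces,
purges dead ones, and keeps each survivor independently with the
triangular mood-congruence probability p = max(0, 1 − γ·|e − ν|): γ = 0
retrieves everything; large γ retrieves only traces whose stored emotion
matches the current mood.  Retrieved traces are refreshed.  Duplicate
traces about the same counterpart are all kept; the expectation averages
over whatever is retrieved.

**Subjective trace content.**  The remembered reward is the *perceived*
one, min(β·c_B, 1), not the objective cooperation level.  This is the
package's central representational choice.  With objective storage,
reward sensitivity touches nothing but the emotion channel; mood (an
exponentially smoothed average of the agent's own emotions) then settles
at the centre of its own trace-emotion distribution, the triangular
kernel selects symmetrically around that centre, and no mechanism
remains by which mania or anhedonia can move cooperation levels —
simulations under that reading showed every memory manipulation
(forgetting rate, encoding bias, mood dependence) changing payoffs by
under 2%.  With subjective storage the appraisal compares like with
like (perceived reward against an expectation formed from perceived
rewards), manic expectations saturate upward and anhedonic ones deflate,
and the memory machinery acquires payoff consequences.  The objective
reading remains available via `subjective_traces=False`.

**Cold start.**  An empty retrieval (first encounter, or total
forgetting) yields an expectation drawn fresh from U[0, 1] (configurable
to a fixed value).  A fixed cold-start value v is a frozen fixed point of
the whole society — everyone cooperates at exactly v forever, because
cooperation equals the average of remembered cooperations — so the
random draw is the minimal symmetry-breaking that gives the dynamics
anything to average.

## Network

The interaction graph is built once per run by randomized stub matching
against the per-agent target degrees.  Depressed agents carry a
connection-diversity quota π (default 0.25): a fraction π of their
neighborhood is wired to other depressed agents first, and the remaining
slots are split equally over the other three types.  π·0.5 must not
exceed the depressed population share (a depressed agent's degree can
reach 0.5·n), otherwise the configuration is rejected.  Random matching
alone strands stubs on high-degree nodes, so a completion phase pairs
remaining deficits directly (largest deficit first) and then rewires
existing edges onto deficit nodes; quota edges are protected from
rewiring so the diversity fraction survives completion.  Realized degrees
land within about 2% of targets on average (tolerance contract: 10%);
unclosable deficits are dropped and reported.  The graph is static for a
run.

## Broadcast gists

Participants' neighbors can receive a secondhand "gist" of each
interaction: the counterpart's cooperation level (filed through the
recipient's own reward sensitivity), neutral emotion, and hence the weak
intercept encoding strength.  Gists are off by default: each store would
otherwise accumulate roughly fifty gists per firsthand trace, and
retrieved sets become almost entirely neutral-emotion secondhand rows,
which empirically drowns the emotional-bias and mood-dependence channels
the model exists to study.  The mechanism is fully implemented and
switchable (`broadcast=True`).

For performance the engine delivers gists lazily: each interaction is
appended once to a public per-agent history, and a recipient's gists
about a counterpart are materialized from that history at its next query
— observationally identical to eager end-of-round delivery (gists become
retrievable the following round; deletion depends only on elapsed time,
so dead gists are never seen), and verified against the eager form in
the test-suite.

## Default memory regime

θ = 0.01 per round and γ = 1, the centres of the sweep grids on the log
scale.  At θ = 0.01 unrefreshed lifetimes are 230 rounds (weakest
encoding) to 450 rounds (strongest), which straddles the typical
pair re-meeting interval of a few hundred rounds — encoding strength,
deletion, and refresh-on-retrieval are all consequential within a
2000-round run.  At θ ≤ 10⁻³ no trace ever dies inside a run and the
encoding-bias experiment returns exactly zero by construction; at θ = 10
the longest-lived trace survives under half a round ("no memory").

## Numerical and engineering choices

- Decay is evaluated as a precomputed expiry time per trace
  (encoded_at + ln(φ₀/φ_min)/θ), so purging is a comparison rather than
  an exponential; refresh pushes the expiry forward.  A cached
  minimum-expiry bound short-circuits purges that cannot delete.
- Stores are column-oriented per (agent, counterpart) with one uniform
  draw per surviving trace in storage order; the Trace-list reference
  implementation consumes the identical stream, and the two are
  draw-for-draw interchangeable (tested).
- Pairing visits active agents in a seeded random order; each unmatched
  agent picks one uniformly random unmatched active neighbor; an agent
  that finds no partner stays available to later pickers.
- One master seed fans out to named substreams (population, network,
  rhythm, activity, pairing, retrieval, cold start), making a run a pure
  function of (config, seed); event logs are byte-identical across
  repeats.
- Degree values round to nearest and cap at n−1; the trait-to-degree map
  extends its manic branch to β⁰ = β_max.
- Replicated experiments reuse the same replicate seeds at every grid
  point (common random numbers), so grid contrasts are paired.

## Experiment sizes

The canned experiments run at the full study scale of 200 agents and
2000 rounds.  The packaged checks use 10 replicate seeds for the default
society, 5 for the forgetting endpoints and bias arms, 4 for the
mood-dependence grid, and 2 for the ten-point trait-sensitivity grid;
engine-contract checks (determinism, conservation, audits) use smaller
societies since they are scale-free.  A single full-scale run takes a
few seconds on one CPU core.

## What the simulations do and do not show

All data are generated by the model itself; there is no external input.
The simulations characterize the model's behavior, not human behavior:
drive, reach, perception, memory and mood are stylized one-parameter
mechanisms, the network is static, types are fixed for life, and payoff
is the only outcome.  Within the model, the packaged experiments compute
(and the tests assert where stated): the strict payoff advantage of
manic over rational over depressed agents and its near-linear
dose-response in β⁰; the payoff cost of losing memory (θ = 10 vs 10⁻⁴),
smallest for manic agents, whose saturated expectations depend least on
remembered detail; and the direction of the encoding-bias and
mood-dependence manipulations.  The magnitudes of several comparative
effects are sensitive to the unconstrained defaults (cold-start rule,
payoff constants, θ, γ) and to the trace-content reading discussed
above; the acceptance script reports the measured values rather than
asserting them.

## Known limitations

- The mood smoother tanh(ν + κ(δ − ν)) equilibrates strictly below the
  mean of the emotions feeding it (double squashing), so strongly manic
  agents' moods sit well below their near-saturated emotions; with the
  triangular kernel this produces a mild downward retrieval bias for
  manic agents rather than an upward one, and interior-γ payoff peaks do
  not arise under the printed update rules.
- Bipolar agents are exploited around phase transitions (their partners'
  expectations lag their rhythm), which roughly cancels their
  manic-phase gains; their net payoff lands near the rational baseline
  with high within-type variance.
- With the default payoff constants C + D = T + S, so the bilinear
  payoff has no interaction term; mutual-cooperation synergy enters only
  through reciprocity dynamics, not through curvature.
- Increasing the share of manic agents raises (not dips) their average
  payoff here: more high-cooperation partners help everyone, and no
  congestion mechanism counteracts it.
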