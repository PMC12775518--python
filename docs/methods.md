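# Methods

## The design model

A design candidate is fully determined by its repeat unit: a string of
length *L* over the 20 canonical amino acids, concatenated *N* times.
The search therefore happens in the 20^L unit space, not the 20^(NL)
sequence space — per-repeat variation is deliberately deferred to the
inverse-folding redesign stage. `choose_repeat_number` picks the
smallest *N* with *N* ≥ 4 whose total length reaches the band minimum
(default band 130–180 residues) and raises if that total overshoots the
band maximum; infeasible combinations fail loudly rather than clipping.

The objective is fitness = (pLDDT + solenoid score)/2, both on 0–1:

- pLDDT: mean over residues within each predictor model, then mean over
  the five models. Adapters convert 0–100 confidence scales to 0–1 at
  the boundary; everything internal is a fraction.
- solenoid score: per model, each residue's class-probability row
  (alpha, beta, alphabeta, non-solenoid — fixed order) is hardened by
  argmax (ties to the lowest index) and the score is the fraction of
  residues assigned to the target class, averaged over models.

The completion gate is deliberately stricter than the objective: every
one of the five models must individually exceed the pLDDT threshold
(default 0.70, strict), and the solenoid score must reach the class
threshold (0.6 for α/β, 0.7 for αβ — mixed repeats below 0.7 tend to
collapse into loop-heavy β-like folds).

## The genetic algorithm

Wright–Fisher parent selection with softmax weights
P(i) ∝ exp(f_i/τ). τ defaults to 0.1: fitness lives on 0–1, so τ = 0.1
makes a 0.1 fitness edge an e-fold selection advantage. Mutation flips
each unit position independently with probability 1/L and resamples a
flipped position uniformly from the 19 other letters (index-shift
sampling, no rejection loop), giving exactly Binomial(L, 1/L) mutations
per offspring — one on average. Replacement is steady-state: a child
enters only if its full sequence is absent from the current population
and its fitness strictly beats the current worst member, which it then
evicts (ties for worst evict the longest-resident member, keeping runs
deterministic). Generation 0 is the random initial population;
`max_generations` (default 30) counts post-initial generations, and the
run stops at the first evaluated candidate — child or initial member —
that passes the gate.

Defaults of population 20 and 10 children per generation make one
generation ≈ 10 oracle calls. Population size interacts with selection
in a way worth stating: because softmax pressure is *relative*, growing
the population at a fixed offspring budget slows convergence in
generations (measured medians 56/72/89/122 at populations 4/10/20/40
with 10 children, hidden-target landscape, L = 6). Larger populations
help only when the offspring budget grows with them — the property
tests scale children as population/2 for exactly this reason.

## Surrogate oracles

The surrogate landscape is parameterised by q, the fraction of
repeat-aligned positions matching a hidden target unit: per-residue
pLDDT of model m is clip(0.2 + 0.8q + δ_m, 0, 1) with fixed per-model
offsets δ ∈ {−0.02, −0.01, 0, +0.01, +0.02}; pTM = q; every pAE entry
is 20(1−q) Å; coordinates come from the parametric solenoid generator
with positional noise shrinking in q, seeded from the sequence itself
so prediction is a pure function of input. The discriminator assigns
the target class probability q and splits the rest evenly. Mean pLDDT
is strictly monotone in q, which is the property the convergence tests
lean on. The non-zero offsets make the "all five models" gate
non-trivial: the worst model sits 0.02 below the ensemble mean, so a
gate of 0.97 is passed only by the exact target unit at L = 6.

What the surrogates do **not** emulate: epistasis (the landscape is
additive in matches), predictor pathologies (overconfident repetitive
artifacts), any physics. Passing tests show the algorithms are correct
against a known landscape; they say nothing about design success with
real oracles.

## Filters

All gates are strict inequalities and pure functions of their inputs.
Designability: RMSD < 5 Å and mean pLDDT > 0.80 for at least one
redesign. Capping cascade (every stage): RMSD < 2 Å, mean pAE < 5 Å
overall and over the cap region alone (the "terminal region" is read as
the designed cap residues; before any cap exists the terminal gate
degenerates to the full-structure one), pLDDT > 0.80 from both
predictors. Final gate: Succ50 > 0.71. Redesign ranking is
lexicographic — designable first, then descending pLDDT, then ascending
RMSD — a documented choice where a combined score would also have been
defensible. The RMSD between a prediction ensemble and a reference uses
the highest-pLDDT member's Cα trace.

Kabsch superposition uses the SVD solution with the determinant
correction (proper rotations only — a mirror image must not score
zero), and computes the RMSD from the rotated residuals rather than the
trace formula, which cancels catastrophically near zero.

Cap sizing: 2L residues, extended to 4L for repeats of length ≤ 5,
whose two-rung caps would otherwise be too short to cover the exposed
cross-section. The secondary-structure conditioning string tiles "HXX"
and truncates (never pads) to the cap length; the tiling phase is a
bias, not a constraint, so truncation is harmless.

## In silico melting

Masking levels run from 0.30 to 0.99; a 0.05 grid from 0.30 cannot land
on 0.99, so the terminal level is appended explicitly (15 levels
total) and the schedule stays configurable. Masked-position counts use
round-half-away-from-zero for cross-platform determinism. At each
level, 64 replicates with fresh uniform masking patterns are
repredicted and a replicate succeeds iff pTM > 0.75 (strict — exactly
0.75 fails). The curve is fitted with the decreasing logistic
s(m) = b + (t−b)/(1 + e^{k(m−m₅₀)}), bounds 0 ≤ b, t ≤ 1, k > 0,
initial guesses t = max rate, b = min rate, m₅₀ = level nearest
half-range, k = 20. The functional form is this package's choice; the
asymptotes are bounded but not pinned. Validity rules: zero dynamic
range or optimiser failure → `fit_failed`; m₅₀ outside [0, 1] →
`out_of_range`; neither produces a usable melting point. Under binomial
noise at 64 replicates, recovery error on m₅₀ is ~0.005 median
(slope 30), comfortably identifying a 0.71 threshold.

## Structure space

Distances are d = 1 − TM (the simplest monotone map onto [0, 1]);
asymmetric query/target-normalised tables are symmetrised by the
maximum of the two directions. MDS is metric SMACOF initialised from
the classical (Torgerson) eigendecomposition, so exactly-embeddable 2D
configurations are recovered at numerically zero stress and the
embedding is seed-deterministic. Greedy clustering repeatedly promotes
the unassigned structure with the most unassigned neighbours at
TM ≥ threshold; it emulates representative-based clustering but exact
agreement with any external tool is not claimed — external cluster
tables can be ingested instead. Mann–Whitney comparisons use the exact
null distribution for small tie-free samples (n₁·n₂ ≤ 400) and the
tie-corrected normal approximation otherwise; literal enumeration of
assignments (the test oracle) is infeasible beyond tiny samples.

## Problem sizes

Tests and the acceptance script run the loop at L = 6, N = 4,
population 20, 10 children, up to 300 generations over 20 seeds
(surrogate oracle calls are microseconds); Kabsch agreement uses 200
random 4–10-point instances against a 60-start rotation search;
melting recovery uses 50 synthetic curves at 64 replicates; the capping
cascade demonstration uses one 40-residue backbone with the full
10 × 10 × 10 fan-out. These sizes exercise every code path while
keeping a full run in well under a minute each.

## Known limitations

- The surrogate landscape is separable; convergence speed on it is an
  upper bound on realistic behaviour.
- Real oracle adapters implement only the availability contract;
  invoking an actual predictor requires subclassing against a local
  installation.
- The GA has no crossover, matching the mutation-only design of the
  loop; multi-objective treatments of the two fitness components are
  out of scope.
- TM-scores are never computed internally — only consumed from
  alignment tables — so structure-space results inherit whatever
  normalisation the external aligner used.
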