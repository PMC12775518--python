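# solenoid-forge

Tools for hallucinating solenoid repeat proteins — tandem-repeat
architectures (α-, β- and αβ-solenoids) whose repeats stack along a
superhelical axis — and for filtering the resulting designs with the
metrics that separate experimentally viable candidates from
high-confidence artifacts. It is aimed at protein designers who want a
fold-specific hallucination loop they can test, seed and reason about
without a GPU in the loop.

## What it does

**Design loop.** A candidate is a repeat unit of length *L* concatenated
*N* times (*N* ≥ 4, total length inside a configurable 130–180 residue
band). A steady-state genetic algorithm evolves the unit: parents are
drawn by Wright–Fisher selection with P(i) ∝ exp(*f<sub>i</sub>*/τ),
children are point-mutated at rate 1/*L* (one expected mutation per
offspring, resampling from the 19 other residues), and distinct children
that beat the current worst member evict it. The fitness is the
equal-weight mean of two 0–1 scores from injected oracles: ensemble
pLDDT from a structure predictor, and the fraction of residues a
solenoid discriminator assigns (by per-residue argmax) to the target
class. A design is finished when all five predictor models exceed the
pLDDT gate (default 0.70) and the solenoid score reaches its class
threshold (0.6 for α/β, 0.7 for αβ); runs are cut off after 30
generations by default.

**Filters.** Designability: a backbone passes if any inverse-folding
redesign repredicts to within 5 Å Cα RMSD (Kabsch superposition, proper
rotations only) with mean pLDDT above 0.80. The β-solenoid capping
cascade (designability → N-cap → C-cap) applies stricter gates at every
stage: RMSD < 2 Å, mean pAE < 5 Å overall and over the cap region
alone, pLDDT > 0.80 from two independent predictors. Final selection
additionally requires an in silico melting point Succ50 > 0.71 and
keeps one representative per structural cluster (TM ≥ 0.7).

**In silico melting.** Mask 30–99 % of the sequence in 5 % steps (64
replicates per level), call a replicate a success when the predicted
pTM exceeds 0.75, fit the success-rate curve with a decreasing
four-parameter logistic *s(m) = b + (t−b)/(1+e^{k(m−m₅₀)})*, and report
the inflection *m₅₀* as Succ50. Unfittable curves and inflections
outside [0, 1] are flagged invalid rather than reported.

**Structure space.** All-vs-all TM-score tables are symmetrised,
converted to distances (*d* = 1 − TM), embedded in 2D by metric MDS
(classical-MDS initialisation + SMACOF), clustered greedily at a TM
threshold, and summarised with novelty fractions (structural: best
match TM < 0.5; sequence: best-hit E-value > 10⁻⁵) and exact
Mann–Whitney comparisons between outcome groups.

All four neural oracles (structure predictor, solenoid discriminator,
inverse-folding designer, cap generator) sit behind protocols.
Deterministic surrogate implementations with a transparent
hidden-target fitness landscape make every algorithm runnable and
testable at desk scale; real adapters raise an explicit error when
their backend is missing instead of silently degrading.

## Worked example

Evolve a β-solenoid with a 6-residue repeat against the surrogate
oracle (which hides a target unit, so convergence is checkable):

```bash
$ solenoid-forge evolve --repeat-length 6 --num-repeats 4 --target-class beta \
      --min-plddt 0.97 --max-generations 300 --seed 3 --out run_demo
outcome=converged generations=81 best_fitness=0.9970
```

The run converged after 81 post-initial generations; the best candidate
reached fitness 0.9970 (the mean of a 0.994 ensemble pLDDT — the top
two surrogate models clip at 1.0 — and a 1.0 solenoid score).
`run_demo/` contains the per-generation trajectory (`trajectory.jsonl`,
`trajectory.csv`), the winning sequence and its structure:

```
$ cat run_demo/best.fasta
>best_design
WFMKLHWFMKLHWFMKLHWFMKLH
```

— the hidden 6-mer `WFMKLH` repeated 4 times. Other subcommands:
`redesign` (rank inverse-folding redesigns by refolding quality),
`cap` (run the capping cascade), `melt` (Succ50 per FASTA record) and
`space` (MDS embedding of a TM-score table).

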