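# Methods notes

## The simulation loop

The unit of evolution is an amino acid sequence over the 20 canonical
residues.  A population of fixed size N advances in discrete generations:

1. every individual produces exactly one mutated copy (one event drawn from
   the evolutionary dictionary),
2. all 2N sequences (parents and offspring) are folded by the configured
   structure backend and scored,
3. N survivors are selected (strong / proportional / Gibbs),
4. the generation is recorded and the stop rule is checked: the run ends
   when any pool member reaches both confidence thresholds (defaults
   pLDDT ≥ 0.85 and pTM ≥ 0.75, both inclusive, on the internal [0, 1]
   scale) or when the generation budget is exhausted.

Keeping parents in the pool makes strong selection elitist: the best
selected score is non-decreasing across generations, which the test suite
asserts on full runs.

## Mutation model

Default event rates (all overridable): substitution 0.88, single insertion
0.04, single deletion 0.04, multi-residue deletion 0.01, random insertion
0.01, partial duplication 0.01, complete duplication 0.005, circular
permutation 0.005.  Substitutions dominate and duplications are rare, as in
protein evolution; the exact non-point rates are a package default rather
than an empirical estimate.  A length-preserving preset
(`FIXED_LENGTH_EVENT_RATES`: 0.90 / 0.05 / 0.05 substitution / single
insertion / single deletion) expresses the fixed-length regime purely as a
rate table — balanced single indels keep the expected length constant, so
no separate code path exists for it.

Multi-residue indel lengths are uniform on [2, 10]; partial duplication
copies a uniformly chosen contiguous segment (length uniform on [2, L/2])
in tandem at its own end; circular permutation allows any internal cut
point 1..L−1.  Hard guards keep chains within [10, 500] residues: an event
that would cross a bound is coerced to a substitution, so the
one-event-per-individual contract is never broken.  Substitution models
never return the original residue — replacement matrices have their
diagonal zeroed and rows renormalised at load time.

## Fitness

`s = ⟨pLDDT⟩ · pTM · CD · (ipLDDT · iCD) · constr`, all terms per the README.
Conventions that required a decision:

- Contact distance is 6.0 Å between C&beta; atoms (glycine contributes its
  C&alpha; as proxy).  Contact pairs are **unordered**; the choice is
  internal-consistent everywhere (an ordered convention would double CD and
  rescale all scores without changing any ranking).
- The sequence-separation filter is strict: |i−j| > 5.  No additional
  secondary-structure exclusion is applied — the separation filter alone
  already removes i,i+4 helical contacts.
- The confidence filter is strict: both residues must have pLDDT > 0.5.
- Interface terms have no separation filter across chains.  An empty
  interface yields ipLDDT = iCD = 0, so a non-interacting dimer scores 0 —
  this is the selection pressure toward binding in partner mode.
- The length constraint multiplies the whole-chain law with one factor per
  maximal helix and strand element.  Applying the penalty per element (as
  opposed to only the longest element) penalises each oversized element
  independently, which matches the multiplicative structure of the score;
  this choice is flagged for sensitivity analysis as the per-element
  combination is a package decision.
- Confidences are canonically [0, 1] in memory; the 0–100 convention exists
  only at the PDB boundary (B-factor column).  This removes the silent
  ×100 bug class by type invariant.

## Selection

- Strong: stable sort by descending score, ties by insertion order, take N.
  A median-threshold formulation fails when ties straddle the median; the
  sort is the primary definition.
- Proportional: N draws with replacement at `p_i = s_i/Σs`; an all-zero
  pool falls back to the uniform distribution.
- Gibbs: softmax with max-shift before exponentiation (exact for the
  normalised probabilities); β = 0 reduces to uniform 1/(2N).
- Both stochastic modes accept `replace=False` (sequential renormalised
  draws).  The large-β limit of with-replacement softmax sampling is N
  copies of the argmax, **not** the top-half set; only the
  without-replacement variant converges to strong selection's survivor set,
  and that variant is what the convergence tests exercise.  The engine's
  default remains with-replacement, where repeat picks become clones: each
  clone gets a fresh identity with a mutation-free edge from the pool
  member it copies, keeping the genealogy a tree rather than a DAG.
  Finite β cannot separate near-ties, so the convergence property is
  stated for distinct, well-separated scores (β·gap ≫ 1).

## The surrogate structure backend

The surrogate is deterministic plumbing that lets the full loop run and be
tested at desk scale.  It emulates exactly the *signals* the fitness
function consumes; it does not emulate physics.

- Per-residue periodicity signals are hydrophobic moments of a 7-residue
  sliding window of z-scored Kyte–Doolittle hydropathy: the helix channel
  at 2 turns / 7 residues (3.5 residues per turn) and the strand channel at
  period 2.  Windows are clamped (not truncated) at the termini, so a
  perfectly periodic segment scores uniformly along its length — this is
  what makes mean confidence non-decreasing in helix length.
- Labels: H where the helix channel dominates above 0.45, E where the
  strand channel dominates above 0.55; runs shorter than 4 (H) or 3 (E)
  are demoted to coil.
- Geometry: helices are ideal (1.5 Å rise, 100° twist, 2.3 Å radius),
  strands are 3.3 Å-rise zig-zags, coil is a self-avoiding random walk with
  a bounded forward cosine (≤ 0.2) so that coil never mimics extended
  strand geometry.  All stochastic geometry derives from CRC32 hashes of
  the 7-residue local sequence context: the map from sequence to structure
  is a pure function, and a point mutation perturbs the trace only locally.
- Confidence: pLDDT = logistic(12 · (signal − 0.5)) per residue.  The
  midpoint sits above the typical aperiodic-window signal so that random,
  disordered sequences read as low-confidence (population mean ≈ 0.38 for
  random 24-mers), as a structure predictor would report; strongly periodic
  segments approach 0.99.  pTM = logistic of mean pLDDT and structured
  fraction.
- Dimer mode translates the evolving chain to a hash-determined offset and
  direction next to the fixed partner, so interface formation is a rugged
  but deterministic function of the evolving sequence.

What the surrogate does *not* reproduce: tertiary packing driven by
physical energetics, cooperative folding, realistic contact orders, or a
smooth sequence→structure landscape (the hash-seeded coil makes the
landscape deliberately rugged).  Passing tests therefore demonstrate the
correctness of the evolutionary machinery — bookkeeping, selection response,
reproducibility — not that evolved surrogate structures resemble proteins.

## Secondary-structure assignment

The default assigner uses only the C&alpha; trace: d13 (CA_i→CA_{i+2}) and
d14 (CA_i→CA_{i+3}) virtual-bond distances fall in disjoint bands for ideal
helices (≈5.4 / ≈5.1 Å) and strands (≈6.6 / ≈10 Å); two consecutive d13
hits plus a d14 hit anchor four residues, helix winning conflicts.  Chains
under 4 residues are all coil.  The assigner is a pluggable callable; tests
cross-check it against an independent P-SEA implementation on ideal
geometry.  The constraint math needs only element labels and lengths, so
any assigner with that interface can be substituted.

## Reproducibility and numerics

- One master seed spawns named child streams (founders, mutation,
  selection) via `numpy` seed sequences; adding draws to one operator never
  shifts another's stream.
- Checkpoints serialise the full engine state — including the PCG64 bit
  generator states — as JSON; resuming reproduces the uninterrupted
  trajectory byte-for-byte, which the tests assert on the TSV run logs.
- Evaluation memoisation (off by default) is keyed by residue string and
  provably changes nothing for deterministic backends; it exists purely as
  a throughput lever and is exercised by an equivalence test.
- Probability vectors are validated to sum to 1 within 1e-12; the fitness
  breakdown re-multiplies to the stored score at machine precision.
- Event rate tables must sum to 1 within 1e-9.

## Problem sizes

The bundled suites run populations of 8–20 for 10–200 generations, with 20
replicates for the selection-response property, and oracle comparisons on
up to 200 random fixtures of ≤ 80 residues — sizes chosen so the entire
suite completes in minutes on one CPU while still exercising every code
path, including full multi-hundred-generation trajectories.  Larger runs
only change wall-clock time; the engine is O(N · L²) per generation,
dominated by structure evaluation and pairwise contact scans.

## Known limitations

- The surrogate's confidence calibration is a design choice, not a fit to
  any predictor's output distribution; absolute stop-time statistics are
  therefore not comparable to runs driven by a neural predictor.
- Mutations-per-site is well-defined only for (nearly) fixed-length runs;
  for variable-length regimes the summary flags the value as approximate
  (`variable_length=True`), since early-run lengths differ from the final
  length used as the denominator.
- Codon-level mutation is out of scope; substitution weighting operates on
  amino acid frequencies supplied by the user.
- No physical energy terms: solvation, electrostatics and side-chain
  packing are outside the score.
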