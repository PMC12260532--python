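# foldevo

Simulation of protein fold evolution from random amino acid sequences.

A fixed-size population of peptides evolves generation by generation: every
individual acquires exactly one mutation (point substitution, single or
multi-residue indel, partial/complete tandem duplication, or circular
permutation), every resulting sequence is folded by a pluggable structure
backend, and N survivors are selected from the mixed pool of 2N parents and
offspring.  The package is aimed at computational biologists studying how
stable, compact folds can nucleate from unstructured sequence under
selection for predicted fold stability — and at anyone who wants a fully
deterministic, desk-scale testbed for that loop.

## The model

Each individual *i* is scored multiplicatively from its predicted structure:

```
s_i = ⟨pLDDT⟩ · pTM · CD · (ipLDDT · iCD) · constr
```

- `⟨pLDDT⟩` — mean per-residue confidence (internal scale [0, 1]),
- `pTM` — global confidence,
- `CD` — long-range contact density: unordered residue pairs with
  C&beta;–C&beta; distance < 6 Å, sequence separation |i−j| > 5 and both
  residues at pLDDT > 0.5, divided by the chain length (the separation
  filter excludes trivial helix i,i+4 contacts),
- `ipLDDT`, `iCD` — interface analogues for an evolving chain bound to a
  fixed partner chain (identity 1 for monomers); iCD is normalised by the
  evolving chain's length,
- `constr` — product of logistic length penalties
  `P(L) = 1 − 1/(1 + e^{C(L0−L)})` on the whole chain (C=0.2, L0=250) and on
  each helix (C=0.5, L0=30) and strand (C=0.5, L0=12) element; a chain or
  element exactly at its midpoint L0 halves the score.

Survivors are chosen by one of three rules: **strong** selection keeps the
deterministic top half; **proportional** selection draws N individuals with
replacement with probability `s_i / Σ s_k`; **Gibbs** selection draws from the
softmax `e^{β s_i} / Σ e^{β s_k}` — β = 0 is neutral drift and large β
approaches strong selection.  A run stops when any individual reaches the
configured confidence thresholds (default pLDDT ≥ 0.85 and pTM ≥ 0.75) or at
the generation budget.  The complete genealogy of every selected individual
is recorded, so the mutations *fixed* on the direct ancestral path of the
first stable protein can be counted and compared with the total mutational
input (N mutations per generation).

The structure backend is a contract, not a dependency: the bundled
deterministic surrogate maps sequence hydropathy periodicity to idealised
helix/strand/coil geometry with matching confidence values, so the whole
loop runs in milliseconds per sequence; an adapter for a neural predictor
only has to return coordinates and confidences for a batch of sequences.

## Worked example

```python
import foldevo as fe

cfg = fe.RunConfig(
    population_size=20,
    founder_length=24,
    max_generations=120,
    seed=42,
    selection=fe.SelectionConfig(mode=fe.SelectionMode.PROPORTIONAL),
)
result = fe.run_simulation(cfg)
stats = fe.summarize_run(result.records, result.tree, cfg)
print("generations:", stats.generations)
print("total mutations:", stats.total_mutations)
print("fixed (lineage) mutations:", stats.fixed_mutations)
print("fixation rate:", round(stats.fixation_rate, 5))
print("mutations per site:", round(stats.mutations_per_site, 3))
print("best score gen 1 -> final:",
      round(result.records[0].best_score, 4),
      round(result.records[-1].best_score, 4))
```

prints

```
generations: 42
total mutations: 840
fixed (lineage) mutations: 7
fixation rate: 0.00833
mutations per site: 0.229
best score gen 1 -> final: 0.3444 1.0437
```

Twenty random 24-mers evolved under fitness-proportional selection; after 42
generations one peptide crossed the confidence thresholds (a nucleated
fold).  840 mutations were tried in total, of which 7 lie on the winning
lineage — a fixation rate of 0.83 %, necessarily ≤ 1/N because at most one
mutation fixes per generation on any single lineage.  The best fitness rose
three-fold, driven by helix content (62 % H in the final population).

The same run from a shell, with per-generation logging, TSV/FASTA/Newick
outputs and a resumable checkpoint:

```
foldevo run --config run.yaml --seed 42 --outdir out/ --checkpoint out/state.json
foldevo summarize --run out/state.json
foldevo lineage --run out/state.json --id <individual>
foldevo score --pdb-dir out/
```

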