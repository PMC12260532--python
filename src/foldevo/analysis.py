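"""Post-hoc statistics on completed runs.

Lineage extraction walks the genealogy from a founder to any selected
individual; the "fixed" mutations of a run are the events on the lineage of
the first individual to satisfy the stop condition (or of the best-scoring
final individual when the run ends on the generation budget).  From those the
fixation rate (fixed / total mutations, with total = N x generations exactly)
and mutations-per-site follow.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .engine import GenerationRecord, RunConfig, SimulationResult
from .lineage import LineageTree
from .mutation import MutationEvent, apply_mutation
from .sequences import ProteinSequence
from .structure import StructureModel


@dataclass(frozen=True)
class SummaryStats:
    """Table-style summary of one run."""

    generations: int
    total_mutations: int
    fixed_mutations: int
    fixation_rate: float
    mean_final_length: float
    mutations_per_site: float
    variable_length: bool  # flagged: mutations/site is approximate for these runs
    per_generation_rg: tuple[float, ...]
    per_generation_ss: tuple[tuple[float, float, float], ...]

    def as_dict(self) -> dict:
        return asdict(self)


def total_mutations(population_size: int, generations: float) -> float:
    """Every individual mutates once per generation: total = N x generations."""
    return population_size * generations


def fixation_rate(fixed: float, total: float) -> float:
    """Fraction of all mutations that lie on the focal lineage."""
    if total <= 0:
        raise ValueError("total mutation count must be positive")
    return fixed / total


def mutations_per_site(fixed: float, mean_length: float) -> float:
    """Lineage mutations per residue of the final protein."""
    if mean_length <= 0:
        raise ValueError("mean length must be positive")
    return fixed / mean_length


def extract_lineage(
    tree: LineageTree, individual_id: str
) -> list[tuple[str, MutationEvent | None]]:
    """Root-to-leaf path as (sequence, event) pairs.

    Edges without a mutation (repeat selections of an unchanged individual)
    are dropped, so consecutive sequences differ by exactly the listed event
    and the path length counts unique sequences only.
    """
    path = tree.path_to_root(individual_id)
    out: list[tuple[str, MutationEvent | None]] = [(path[0].sequence, None)]
    for node in path[1:]:
        if node.event is None:
            continue  # clone of an unchanged parent
        out.append((node.sequence, node.event))
    return out


def replay_lineage(lineage: list[tuple[str, MutationEvent | None]]) -> str:
    """Re-apply the event list to the founder; returns the reconstructed leaf."""
    seq = ProteinSequence(id="replay", residues=lineage[0][0])
    for _, event in lineage[1:]:
        seq = apply_mutation(seq, event)
    return seq.residues


def focal_individual(result: SimulationResult) -> str:
    """The individual whose lineage defines the run's fixed mutations.

    First selected individual to satisfy the stop condition (ties broken by
    higher score, then stable order); if the run never stopped, the
    best-scoring selected individual of the final generation.
    """
    cfg = result.config
    for rec in result.records:
        if not rec.stop_reached:
            continue
        hits = [
            m
            for m in rec.members
            if m.selected
            and m.breakdown.plddt_mean >= cfg.plddt_stop
            and m.breakdown.ptm >= cfg.ptm_stop
        ]
        if hits:
            return max(hits, key=lambda m: m.breakdown.score).id
    final = result.records[-1]
    chosen = [m for m in final.members if m.selected]
    return max(chosen, key=lambda m: m.breakdown.score).id


def summarize_run(
    records: list[GenerationRecord],
    tree: LineageTree,
    config: RunConfig,
) -> SummaryStats:
    """Compute the run-level statistics table."""
    if not records:
        raise ValueError("no generation records")
    result = SimulationResult(
        config=config,
        final_population=[],
        tree=tree,
        records=records,
        stopped_early=records[-1].stop_reached,
    )
    gens = len(records)
    total = int(total_mutations(config.population_size, gens))
    focal = focal_individual(result)
    lineage = extract_lineage(tree, _tree_ancestor_of(tree, focal))
    fixed = sum(1 for _, ev in lineage[1:] if ev is not None)
    mean_len = float(records[-1].mean_length)
    fixed_length_regime = all(
        m.event.startswith(("SUB", "INS1", "DEL1", "."))
        for rec in records
        for m in rec.members
    )
    return SummaryStats(
        generations=gens,
        total_mutations=total,
        fixed_mutations=fixed,
        fixation_rate=fixation_rate(fixed, total),
        mean_final_length=mean_len,
        mutations_per_site=mutations_per_site(fixed, mean_len),
        variable_length=not fixed_length_regime,
        per_generation_rg=tuple(r.mean_rg for r in records),
        per_generation_ss=tuple(r.ss_fractions for r in records),
    )


def _tree_ancestor_of(tree: LineageTree, individual_id: str) -> str:
    # pool members that were never selected are not tree nodes; fall back to
    # their parent (same lineage minus the terminal event)
    if individual_id in tree:
        return individual_id
    raise KeyError(f"individual {individual_id} not in lineage tree")


def radius_of_gyration(model: StructureModel, chain: str | None = None) -> float:
    """Unweighted CA radius of gyration in Angstroms."""
    ca = model.ca(chain or model.chains[0])
    centroid = ca.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((ca - centroid) ** 2, axis=1))))


def ss_composition(annotations) -> list[tuple[float, float, float]]:
    """Per-generation (H, E, C) fractions; each triple sums to 1.

    ``annotations`` is an iterable of per-generation iterables of
    SecondaryStructureAnnotation (or plain label strings).
    """
    out = []
    for generation in annotations:
        labels = "".join(
            a if isinstance(a, str) else a.labels for a in generation
        )
        L = max(len(labels), 1)
        out.append(
            (labels.count("H") / L, labels.count("E") / L, labels.count("C") / L)
        )
    return out
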