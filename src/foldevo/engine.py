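"""The generation loop: mutate N, evaluate 2N, select N, record everything.

Every run is fully reproducible from a single master seed: the seed spawns
named, independent RNG streams (founders, mutation, selection) so that the
draw order of one operator never shifts another's.  The engine checkpoints
its complete state (population, RNG streams, lineage, records) to JSON and
resumes bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitness import (
    ConstraintParams,
    FitnessBreakdown,
    SigmoidLaw,
    fitness_score,
)
from .lineage import LineageTree
from .mutation import (
    EvolutionaryDictionary,
    MIN_LENGTH,
    MAX_LENGTH,
    apply_mutation,
    draw_mutation,
    make_founders,
)
from .secondary import assign_secondary_structure
from .selection import SelectionConfig, SelectionMode, select
from .sequences import ProteinSequence, write_fasta
from .structure import StructureModel, read_structure, write_structure
from .surrogate import SurrogateEvaluator


class EvaluationError(RuntimeError):
    """Raised when a structure backend fails; names the offending sequence."""


@dataclass
class RunConfig:
    population_size: int = 100
    founder_mode: str = "n_random"
    founder_length: int = 24
    founder_sequence: str | None = None
    dictionary: EvolutionaryDictionary = field(default_factory=EvolutionaryDictionary)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    constraints: ConstraintParams | None = field(default_factory=ConstraintParams)
    evaluator: str = "surrogate"
    partner_pdb: str | None = None
    plddt_stop: float = 0.85
    ptm_stop: float = 0.75
    max_generations: int = 100
    seed: int = 0
    min_length: int = MIN_LENGTH
    max_length: int = MAX_LENGTH
    cache_evaluations: bool = False
    snapshot_every: int | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        if self.max_generations < 1:
            raise ValueError("max generations must be >= 1")
        for t in (self.plddt_stop, self.ptm_stop):
            if not 0.0 <= t <= 1.0:
                raise ValueError("stop thresholds must lie in [0, 1]")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        c = self.constraints
        return {
            "population_size": self.population_size,
            "founder_mode": self.founder_mode,
            "founder_length": self.founder_length,
            "founder_sequence": self.founder_sequence,
            "dictionary": self.dictionary.to_dict(),
            "selection": {
                "mode": self.selection.mode.value,
                "beta": self.selection.beta,
                "replace": self.selection.replace,
            },
            "constraints": None
            if c is None
            else {
                "protein": [c.protein.steepness, c.protein.midpoint],
                "helix": [c.helix.steepness, c.helix.midpoint],
                "strand": [c.strand.steepness, c.strand.midpoint],
            },
            "evaluator": self.evaluator,
            "partner_pdb": self.partner_pdb,
            "plddt_stop": self.plddt_stop,
            "ptm_stop": self.ptm_stop,
            "max_generations": self.max_generations,
            "seed": self.seed,
            "min_length": self.min_length,
            "max_length": self.max_length,
            "cache_evaluations": self.cache_evaluations,
            "snapshot_every": self.snapshot_every,
            "outdir": self.outdir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "dictionary" in d and isinstance(d["dictionary"], dict):
            d["dictionary"] = EvolutionaryDictionary.from_dict(d["dictionary"])
        if "selection" in d and isinstance(d["selection"], dict):
            s = d["selection"]
            d["selection"] = SelectionConfig(
                mode=SelectionMode(s.get("mode", "proportional")),
                beta=s.get("beta", 1.0),
                replace=s.get("replace", True),
            )
        if "constraints" in d:
            c = d["constraints"]
            if isinstance(c, dict):
                d["constraints"] = ConstraintParams(
                    protein=SigmoidLaw(*c["protein"]),
                    helix=SigmoidLaw(*c["helix"]),
                    strand=SigmoidLaw(*c["strand"]),
                )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class PoolRecord:
    """One pool member of one generation."""

    id: str
    parent_id: str | None
    event: str
    breakdown: FitnessBreakdown
    times_selected: int = 0

    @property
    def selected(self) -> bool:
        return self.times_selected > 0


@dataclass
class GenerationRecord:
    generation: int
    members: list[PoolRecord]
    best_score: float
    median_score: float
    mean_length: float
    mean_rg: float
    ss_fractions: tuple[float, float, float]  # H, E, C over the selected set
    stop_reached: bool


def batch_evaluate(sequences, evaluator, batch_size: int | None = None) -> list:
    """Evaluate in input order, chunked by the evaluator's batch size.

    Batching is a throughput contract only: for a deterministic evaluator the
    result is identical to one-at-a-time evaluation.  Backend errors are
    re-raised with the offending sequence's id.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("nothing to evaluate")
    size = batch_size or getattr(evaluator, "batch_size", len(sequences)) or 1
    out = []
    for start in range(0, len(sequences), size):
        chunk = sequences[start : start + size]
        try:
            models = evaluator.evaluate(chunk)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            ids = [getattr(s, "id", "?") for s in chunk]
            raise EvaluationError(f"evaluation failed for batch {ids}: {exc}") from exc
        if len(models) != len(chunk):
            raise EvaluationError("evaluator returned wrong number of models")
        out.extend(models)
    return out


def _float(x: float) -> str:
    return format(x, ".10g")


class EvolutionEngine:
    """Stateful driver; use :func:`run_simulation` for the one-shot path."""

    def __init__(self, config: RunConfig, evaluator=None):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        founders_ss, mutation_ss, selection_ss = ss.spawn(3)
        self._rng_mutation = np.random.default_rng(mutation_ss)
        self._rng_selection = np.random.default_rng(selection_ss)
        self.evaluator = evaluator or self._build_evaluator()
        self.generation = 0
        self.stopped = False
        self._id_counter = 0
        self._cache: dict[str, StructureModel] = {}
        founders_rng = np.random.default_rng(founders_ss)
        self.population = make_founders(
            config.founder_mode,
            config.founder_length,
            config.population_size,
            founders_rng,
            dictionary=config.dictionary,
            seed_sequence=config.founder_sequence,
            min_length=config.min_length,
        )
        self.tree = LineageTree()
        for f in self.population:
            self.tree.add_node(f.id, f.residues, 0)
        self.records: list[GenerationRecord] = []

    def _build_evaluator(self):
        if self.config.evaluator != "surrogate":
            raise ValueError(
                f"unknown evaluator {self.config.evaluator!r}; pass an Evaluator "
                "object for custom backends"
            )
        partner = (
            read_structure(self.config.partner_pdb) if self.config.partner_pdb else None
        )
        return SurrogateEvaluator(partner=partner)

    def _next_id(self, gen: int) -> str:
        self._id_counter += 1
        return f"g{gen}i{self._id_counter}"

    def _evaluate(self, pool) -> list[StructureModel]:
        if not self.config.cache_evaluations:
            return batch_evaluate(pool, self.evaluator)
        missing = [s for s in pool if s.residues not in self._cache]
        if missing:
            for s, m in zip(missing, batch_evaluate(missing, self.evaluator)):
                self._cache[s.residues] = m
        return [self._cache[s.residues] for s in pool]

    def step(self) -> GenerationRecord:
        """Advance one generation; returns its record."""
        if self.stopped:
            raise RuntimeError("run already stopped")
        cfg = self.config
        gen = self.generation + 1
        n = cfg.population_size

        offspring = []
        for parent in self.population:
            ev = draw_mutation(
                parent,
                cfg.dictionary,
                self._rng_mutation,
                min_length=cfg.min_length,
                max_length=cfg.max_length,
            )
            offspring.append(apply_mutation(parent, ev, new_id=self._next_id(gen)))
            offspring[-1] = (offspring[-1], ev)

        pool = list(self.population) + [c for c, _ in offspring]
        events: dict[str, object] = {c.id: e for c, e in offspring}

        models = self._evaluate(pool)
        annotations = [assign_secondary_structure(m, "A") for m in models]
        breakdowns = [
            fitness_score(s, m, cfg.constraints, "A", ss=a)
            for s, m, a in zip(pool, models, annotations)
        ]
        scores = np.array([b.score for b in breakdowns])

        stop_now = any(
            float(m.plddt[m.chain_mask("A")].mean()) >= cfg.plddt_stop
            and m.ptm >= cfg.ptm_stop
            for m in models
        )

        chosen = select(scores, n, cfg.selection, self._rng_selection)

        rows = [
            PoolRecord(
                id=s.id,
                parent_id=s.parent_id,
                event=events[s.id].describe() if s.id in events else ".",
                breakdown=b,
            )
            for s, b in zip(pool, breakdowns)
        ]

        survivors: list[ProteinSequence] = []
        for idx in chosen:
            member = pool[idx]
            rows[idx].times_selected += 1
            first = rows[idx].times_selected == 1
            if first:
                if member.id not in self.tree:  # an offspring, new node
                    self.tree.add_node(
                        member.id,
                        member.residues,
                        gen,
                        parent_id=member.parent_id,
                        event=events[member.id],
                    )
                survivors.append(member)
            else:  # repeat pick: clone with a fresh id, no mutation on the edge
                clone_id = self._next_id(gen)
                if member.id not in self.tree:
                    self.tree.add_node(
                        member.id,
                        member.residues,
                        gen,
                        parent_id=member.parent_id,
                        event=events[member.id],
                    )
                self.tree.add_node(
                    clone_id, member.residues, gen, parent_id=member.id, event=None
                )
                survivors.append(
                    ProteinSequence(
                        id=clone_id,
                        residues=member.residues,
                        generation=gen,
                        parent_id=member.id,
                    )
                )

        sel_idx = [i for i, r in enumerate(rows) if r.selected]
        sel_scores = scores[sel_idx]
        sel_labels = "".join(annotations[i].labels for i in sel_idx)
        rgs = [
            _radius_of_gyration_ca(models[i].ca("A")) for i in sel_idx
        ]
        L = max(len(sel_labels), 1)
        record = GenerationRecord(
            generation=gen,
            members=rows,
            best_score=float(scores.max()),
            median_score=float(np.median(scores)),
            mean_length=float(np.mean([len(pool[i]) for i in sel_idx])),
            mean_rg=float(np.mean(rgs)),
            ss_fractions=(
                sel_labels.count("H") / L,
                sel_labels.count("E") / L,
                sel_labels.count("C") / L,
            ),
            stop_reached=stop_now,
        )
        self.records.append(record)
        self.population = survivors
        self.generation = gen
        if stop_now:
            self.stopped = True
        return record

    def run(self, progress: bool = False) -> "SimulationResult":
        while not self.stopped and self.generation < self.config.max_generations:
            rec = self.step()
            if progress:
                h, e, c = rec.ss_fractions
                print(
                    f"gen {rec.generation:5d}  best={rec.best_score:.4f}  "
                    f"median={rec.median_score:.4f}  len={rec.mean_length:.1f}  "
                    f"rg={rec.mean_rg:.1f}  H/E/C={h:.2f}/{e:.2f}/{c:.2f}"
                )
            if self.config.snapshot_every and self.config.outdir:
                if rec.generation % self.config.snapshot_every == 0:
                    self._snapshot(rec.generation)
        result = SimulationResult(
            config=self.config,
            final_population=list(self.population),
            tree=self.tree,
            records=list(self.records),
            stopped_early=self.stopped,
        )
        if self.config.outdir:
            result.write_outputs(self.config.outdir)
        return result

    def _snapshot(self, gen: int) -> None:
        """Write the current best survivor's structure as a PDB snapshot."""
        models = self._evaluate(self.population)
        scores = [
            fitness_score(s, m, self.config.constraints, "A").score
            for s, m in zip(self.population, models)
        ]
        best = int(np.argmax(scores))
        out = Path(self.config.outdir) / f"best_gen{gen:05d}.pdb"
        out.parent.mkdir(parents=True, exist_ok=True)
        write_structure(models[best], out)

    # -- checkpointing ------------------------------------------------------

    def checkpoint(self, path) -> None:
        state = {
            "version": __version__,
            "config": self.config.to_dict(),
            "generation": self.generation,
            "stopped": self.stopped,
            "id_counter": self._id_counter,
            "rng_mutation": _rng_state(self._rng_mutation),
            "rng_selection": _rng_state(self._rng_selection),
            "population": [
                {
                    "id": s.id,
                    "residues": s.residues,
                    "generation": s.generation,
                    "parent_id": s.parent_id,
                }
                for s in self.population
            ],
            "tree": self.tree.to_dict(),
            "records": [_record_to_dict(r) for r in self.records],
        }
        Path(path).write_text(json.dumps(state))

    @classmethod
    def resume(cls, path, evaluator=None) -> "EvolutionEngine":
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"no checkpoint at {path}")
        try:
            state = json.loads(p.read_text())
            config = RunConfig.from_dict(state["config"])
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise ValueError(f"corrupt checkpoint {path}: {exc}") from exc
        engine = cls.__new__(cls)
        engine.config = config
        engine.evaluator = evaluator or EvolutionEngine._build_evaluator(engine)
        try:
            engine.generation = state["generation"]
            engine.stopped = state["stopped"]
            engine._id_counter = state["id_counter"]
            engine._rng_mutation = _rng_from_state(state["rng_mutation"])
            engine._rng_selection = _rng_from_state(state["rng_selection"])
            engine._cache = {}
            engine.population = [
                ProteinSequence(
                    id=s["id"],
                    residues=s["residues"],
                    generation=s["generation"],
                    parent_id=s["parent_id"],
                )
                for s in state["population"]
            ]
            engine.tree = LineageTree.from_dict(state["tree"])
            engine.records = [_record_from_dict(r) for r in state["records"]]
        except (KeyError, TypeError) as exc:
            last = state.get("generation", "unknown")
            raise ValueError(
                f"corrupt checkpoint {path} (last valid generation: {last}): {exc}"
            ) from exc
        return engine


@dataclass
class SimulationResult:
    config: RunConfig
    final_population: list[ProteinSequence]
    tree: LineageTree
    records: list[GenerationRecord]
    stopped_early: bool

    @property
    def generations(self) -> int:
        return len(self.records)

    def records_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            for m in rec.members:
                rows.append(
                    {
                        "generation": rec.generation,
                        "id": m.id,
                        "parent": m.parent_id or ".",
                        "event": m.event,
                        **{k: _float(v) for k, v in m.breakdown.as_dict().items()},
                        "selected": int(m.times_selected),
                    }
                )
        return pd.DataFrame(rows)

    def write_outputs(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records_frame().to_csv(out / "generations.tsv", sep="\t", index=False)
        write_fasta(self.final_population, out / "final_population.fasta")
        (out / "lineage.nwk").write_text(self.tree.to_newick() + "\n")
        pd.DataFrame(self.tree.edge_table()).to_csv(
            out / "lineage_edges.tsv", sep="\t", index=False
        )
        manifest = {
            "package": "foldevo",
            "version": __version__,
            "seed": self.config.seed,
            "generations_run": self.generations,
            "stopped_early": self.stopped_early,
            "config": self.config.to_dict(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_simulation(config: RunConfig, evaluator=None, progress: bool = False):
    """Run a configured simulation end to end.

    Returns ``(final population, LineageTree, records)`` wrapped in a
    :class:`SimulationResult`.
    """
    return EvolutionEngine(config, evaluator=evaluator).run(progress=progress)


# -- helpers ----------------------------------------------------------------


def _radius_of_gyration_ca(ca: np.ndarray) -> float:
    centroid = ca.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((ca - centroid) ** 2, axis=1))))


def _rng_state(rng: np.random.Generator) -> dict:
    return json.loads(json.dumps(rng.bit_generator.state))


def _rng_from_state(state: dict) -> np.random.Generator:
    bg = np.random.PCG64()
    bg.state = state
    return np.random.Generator(bg)


def _record_to_dict(r: GenerationRecord) -> dict:
    return {
        "generation": r.generation,
        "members": [
            {
                "id": m.id,
                "parent_id": m.parent_id,
                "event": m.event,
                "breakdown": m.breakdown.as_dict(),
                "times_selected": m.times_selected,
            }
            for m in r.members
        ],
        "best_score": r.best_score,
        "median_score": r.median_score,
        "mean_length": r.mean_length,
        "mean_rg": r.mean_rg,
        "ss_fractions": list(r.ss_fractions),
        "stop_reached": r.stop_reached,
    }


def _record_from_dict(d: dict) -> GenerationRecord:
    return GenerationRecord(
        generation=d["generation"],
        members=[
            PoolRecord(
                id=m["id"],
                parent_id=m["parent_id"],
                event=m["event"],
                breakdown=FitnessBreakdown(**m["breakdown"]),
                times_selected=m["times_selected"],
            )
            for m in d["members"]
        ],
        best_score=d["best_score"],
        median_score=d["median_score"],
        mean_length=d["mean_length"],
        mean_rg=d["mean_rg"],
        ss_fractions=tuple(d["ss_fractions"]),
        stop_reached=d["stop_reached"],
    )
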