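"""Mutation operators and the evolutionary dictionary.

Each individual mutates exactly once per generation.  The event type is drawn
from an "evolutionary dictionary": a rate table over eight event types
(point substitution, single/multi indels, random insertions, partial and
complete tandem duplications, circular permutation), a substitution model
(uniform, target-frequency weighted, or a 20x20 row-stochastic replacement
matrix), and a length law for multi-residue indels.

Hard length guards keep chains between a configurable minimum (default 10)
and maximum (default 500): an event that would cross either bound is coerced
to a point substitution instead of being silently skipped, so the one-event-
per-individual contract always holds.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import yaml

from .sequences import AMINO_ACIDS, ProteinSequence, random_residues

#: Hard floor on chain length; deletions that would cross it are coerced.
MIN_LENGTH = 10
#: Hard ceiling on chain length (twice the length-constraint midpoint).
MAX_LENGTH = 500

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class MutationType(Enum):
    SUBSTITUTION = "SUBSTITUTION"
    SINGLE_INSERTION = "SINGLE_INSERTION"
    SINGLE_DELETION = "SINGLE_DELETION"
    MULTI_DELETION = "MULTI_DELETION"
    RANDOM_INSERTION = "RANDOM_INSERTION"
    PARTIAL_DUPLICATION = "PARTIAL_DUPLICATION"
    COMPLETE_DUPLICATION = "COMPLETE_DUPLICATION"
    CIRCULAR_PERMUTATION = "CIRCULAR_PERMUTATION"


@dataclass(frozen=True)
class MutationEvent:
    """A single mutation, fully specified against the pre-mutation sequence.

    ``position`` is a 0-based index into the pre-mutation sequence (for
    insertions, the slot before which the payload is inserted, 0..L).
    ``end`` is the exclusive end of the affected range for multi-residue
    deletions and partial duplications.  ``payload`` holds inserted or
    substituted residues.
    """

    type: MutationType
    position: int = 0
    end: int | None = None
    payload: str = ""

    def describe(self) -> str:
        """Compact single-token description, e.g. ``SUB@4:K``."""
        t = {
            MutationType.SUBSTITUTION: "SUB",
            MutationType.SINGLE_INSERTION: "INS1",
            MutationType.SINGLE_DELETION: "DEL1",
            MutationType.MULTI_DELETION: "DELM",
            MutationType.RANDOM_INSERTION: "INSM",
            MutationType.PARTIAL_DUPLICATION: "DUPP",
            MutationType.COMPLETE_DUPLICATION: "DUPC",
            MutationType.CIRCULAR_PERMUTATION: "CPERM",
        }[self.type]
        span = f"{self.position}" if self.end is None else f"{self.position}-{self.end}"
        return f"{t}@{span}" + (f":{self.payload}" if self.payload else "")


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------


class SubstitutionModel:
    """Draws a replacement residue; never returns the original."""

    kind = "uniform"

    def draw(self, original: str, rng: np.random.Generator) -> str:
        i = rng.integers(0, 19)
        alt = AMINO_ACIDS.replace(original, "")
        return alt[i]

    def row(self, original: str) -> np.ndarray:
        """Replacement distribution over the 20 residues (0 on the original)."""
        p = np.full(20, 1.0 / 19.0)
        p[_AA_INDEX[original]] = 0.0
        return p

    def to_dict(self) -> dict:
        return {"kind": self.kind}


class FrequencySubstitution(SubstitutionModel):
    """Replacement weighted by target residue frequencies (original excluded)."""

    kind = "frequency"

    def __init__(self, frequencies: dict[str, float]):
        f = np.array([frequencies[a] for a in AMINO_ACIDS], dtype=float)
        if np.any(f < 0) or f.sum() <= 0:
            raise ValueError("frequencies must be non-negative and not all zero")
        self.frequencies = f / f.sum()

    def row(self, original: str) -> np.ndarray:
        p = self.frequencies.copy()
        p[_AA_INDEX[original]] = 0.0
        s = p.sum()
        if s <= 0:
            raise ValueError(f"no admissible replacement for {original}")
        return p / s

    def draw(self, original: str, rng: np.random.Generator) -> str:
        return AMINO_ACIDS[rng.choice(20, p=self.row(original))]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "frequencies": {a: float(f) for a, f in zip(AMINO_ACIDS, self.frequencies)},
        }


class MatrixSubstitution(SubstitutionModel):
    """Replacement from a 20x20 row-stochastic table.

    The diagonal is zeroed and rows renormalised at construction so the
    no-self-replacement invariant holds even for matrices with self-rates.
    """

    kind = "matrix"

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (20, 20) or np.any(m < 0):
            raise ValueError("substitution matrix must be 20x20 and non-negative")
        m = m.copy()
        np.fill_diagonal(m, 0.0)
        sums = m.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("every matrix row needs off-diagonal mass")
        self.matrix = m / sums[:, None]

    def row(self, original: str) -> np.ndarray:
        return self.matrix[_AA_INDEX[original]]

    def draw(self, original: str, rng: np.random.Generator) -> str:
        return AMINO_ACIDS[rng.choice(20, p=self.row(original))]

    @classmethod
    def from_table(cls, path) -> "MatrixSubstitution":
        """Read a whitespace-delimited 20x20 table with a one-letter header row.

        Rows may carry a leading row-label column; columns are reordered to
        the canonical alphabet.
        """
        lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
        header = [tok.upper() for tok in lines[0]]
        if sorted(header) != sorted(AMINO_ACIDS):
            raise ValueError("header row must list the 20 one-letter codes")
        col = {a: j for j, a in enumerate(header)}
        body = lines[1:]
        if len(body) != 20:
            raise ValueError("expected 20 matrix rows after the header")
        m = np.zeros((20, 20))
        cols = [_AA_INDEX[a] for a in header]
        for k, ln in enumerate(body):
            if len(ln) == 21:  # leading row label
                row_label, vals = ln[0].upper(), ln[1:]
            elif len(ln) == 20:  # rows in header order
                row_label, vals = header[k], ln
            else:
                raise ValueError("each matrix row needs 20 values (plus optional label)")
            m[_AA_INDEX[row_label], cols] = [float(v) for v in vals]
        return cls(m)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "matrix": self.matrix.tolist()}


def substitution_model_from_dict(d: dict) -> SubstitutionModel:
    kind = d.get("kind", "uniform")
    if kind == "uniform":
        return SubstitutionModel()
    if kind == "frequency":
        return FrequencySubstitution(d["frequencies"])
    if kind == "matrix":
        return MatrixSubstitution(np.asarray(d["matrix"]))
    raise ValueError(f"unknown substitution model kind {kind!r}")


# ---------------------------------------------------------------------------
# Evolutionary dictionary
# ---------------------------------------------------------------------------

#: Default event rates: substitutions dominate, duplications are rare.
DEFAULT_EVENT_RATES: dict[MutationType, float] = {
    MutationType.SUBSTITUTION: 0.88,
    MutationType.SINGLE_INSERTION: 0.04,
    MutationType.SINGLE_DELETION: 0.04,
    MutationType.MULTI_DELETION: 0.01,
    MutationType.RANDOM_INSERTION: 0.01,
    MutationType.PARTIAL_DUPLICATION: 0.01,
    MutationType.COMPLETE_DUPLICATION: 0.005,
    MutationType.CIRCULAR_PERMUTATION: 0.005,
}

#: Length-preserving regime: point mutations and single indels only.
FIXED_LENGTH_EVENT_RATES: dict[MutationType, float] = {
    MutationType.SUBSTITUTION: 0.90,
    MutationType.SINGLE_INSERTION: 0.05,
    MutationType.SINGLE_DELETION: 0.05,
}


@dataclass
class EvolutionaryDictionary:
    """Rate table over mutation event types plus the substitution model.

    ``indel_length_law`` is the inclusive (low, high) range of the uniform
    length distribution used for multi-residue deletions and random
    insertions.
    """

    event_rates: dict[MutationType, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_RATES)
    )
    substitution_model: SubstitutionModel = field(default_factory=SubstitutionModel)
    indel_length_law: tuple[int, int] = (2, 10)

    def __post_init__(self) -> None:
        rates = {
            (MutationType(k) if not isinstance(k, MutationType) else k): float(v)
            for k, v in self.event_rates.items()
        }
        total = sum(rates.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event rates sum to {total}, expected 1 within 1e-9")
        if any(v < 0 for v in rates.values()):
            raise ValueError("event rates must be non-negative")
        lo, hi = self.indel_length_law
        if not (2 <= lo <= hi):
            raise ValueError("indel length law must satisfy 2 <= low <= high")
        self.event_rates = rates
        self._types = list(rates)
        self._probs = np.array([rates[t] for t in self._types])

    def draw_event_type(self, rng: np.random.Generator) -> MutationType:
        return self._types[rng.choice(len(self._types), p=self._probs)]

    def draw_indel_length(self, rng: np.random.Generator) -> int:
        lo, hi = self.indel_length_law
        return int(rng.integers(lo, hi + 1))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "event_rates": {t.value: v for t, v in self.event_rates.items()},
            "substitution_model": self.substitution_model.to_dict(),
            "indel_length_law": list(self.indel_length_law),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvolutionaryDictionary":
        return cls(
            event_rates={MutationType(k): v for k, v in d["event_rates"].items()},
            substitution_model=substitution_model_from_dict(
                d.get("substitution_model", {"kind": "uniform"})
            ),
            indel_length_law=tuple(d.get("indel_length_law", (2, 10))),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_file(cls, path) -> "EvolutionaryDictionary":
        text = Path(path).read_text()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Drawing and applying events
# ---------------------------------------------------------------------------


def draw_mutation(
    seq: ProteinSequence,
    dictionary: EvolutionaryDictionary,
    rng: np.random.Generator,
    min_length: int = MIN_LENGTH,
    max_length: int = MAX_LENGTH,
) -> MutationEvent:
    """Draw exactly one mutation event for ``seq``.

    Events that would push the chain outside [min_length, max_length] are
    coerced to a substitution at a uniform position, so every call yields a
    valid event.
    """
    L = len(seq)
    if L == 0:
        raise ValueError("cannot mutate an empty sequence")
    ev_type = dictionary.draw_event_type(rng)

    def as_substitution() -> MutationEvent:
        pos = int(rng.integers(0, L))
        new = dictionary.substitution_model.draw(seq.residues[pos], rng)
        return MutationEvent(MutationType.SUBSTITUTION, position=pos, payload=new)

    if ev_type is MutationType.SUBSTITUTION:
        return as_substitution()

    if ev_type is MutationType.SINGLE_INSERTION:
        if L + 1 > max_length:
            return as_substitution()
        pos = int(rng.integers(0, L + 1))
        aa = AMINO_ACIDS[rng.integers(0, 20)]
        return MutationEvent(ev_type, position=pos, payload=aa)

    if ev_type is MutationType.SINGLE_DELETION:
        if L - 1 < min_length:
            return as_substitution()
        return MutationEvent(ev_type, position=int(rng.integers(0, L)))

    if ev_type is MutationType.MULTI_DELETION:
        k = dictionary.draw_indel_length(rng)
        if L - k < min_length or k >= L:
            return as_substitution()
        start = int(rng.integers(0, L - k + 1))
        return MutationEvent(ev_type, position=start, end=start + k)

    if ev_type is MutationType.RANDOM_INSERTION:
        k = dictionary.draw_indel_length(rng)
        if L + k > max_length:
            return as_substitution()
        pos = int(rng.integers(0, L + 1))
        return MutationEvent(ev_type, position=pos, payload=random_residues(k, rng))

    if ev_type is MutationType.PARTIAL_DUPLICATION:
        if L < 4:
            return as_substitution()
        k = int(rng.integers(2, max(L // 2, 2) + 1))
        if L + k > max_length:
            return as_substitution()
        start = int(rng.integers(0, L - k + 1))
        return MutationEvent(ev_type, position=start, end=start + k)

    if ev_type is MutationType.COMPLETE_DUPLICATION:
        if 2 * L > max_length:
            return as_substitution()
        return MutationEvent(ev_type, position=0, end=L)

    if ev_type is MutationType.CIRCULAR_PERMUTATION:
        if L < 2:
            return as_substitution()
        cut = int(rng.integers(1, L))
        return MutationEvent(ev_type, position=cut)

    raise AssertionError(f"unhandled event type {ev_type}")


_clone_counter = itertools.count()


def apply_mutation(
    seq: ProteinSequence, event: MutationEvent, new_id: str | None = None
) -> ProteinSequence:
    """Apply one event, returning a child sequence with provenance set."""
    r, L = seq.residues, len(seq)
    t = event.type
    p = event.position

    if t is MutationType.SUBSTITUTION:
        if not 0 <= p < L:
            raise IndexError(f"substitution position {p} out of range for length {L}")
        child = r[:p] + event.payload + r[p + 1 :]
    elif t is MutationType.SINGLE_INSERTION:
        if not 0 <= p <= L:
            raise IndexError(f"insertion position {p} out of range for length {L}")
        child = r[:p] + event.payload + r[p:]
    elif t is MutationType.SINGLE_DELETION:
        if not 0 <= p < L:
            raise IndexError(f"deletion position {p} out of range for length {L}")
        child = r[:p] + r[p + 1 :]
    elif t is MutationType.MULTI_DELETION:
        if event.end is None or not 0 <= p < event.end <= L:
            raise IndexError(f"deletion range {p}:{event.end} invalid for length {L}")
        child = r[:p] + r[event.end :]
    elif t is MutationType.RANDOM_INSERTION:
        if not 0 <= p <= L:
            raise IndexError(f"insertion position {p} out of range for length {L}")
        child = r[:p] + event.payload + r[p:]
    elif t is MutationType.PARTIAL_DUPLICATION:
        if event.end is None or not 0 <= p < event.end <= L:
            raise IndexError(f"duplication range {p}:{event.end} invalid for length {L}")
        child = r[: event.end] + r[p : event.end] + r[event.end :]
    elif t is MutationType.COMPLETE_DUPLICATION:
        child = r + r
    elif t is MutationType.CIRCULAR_PERMUTATION:
        if not 0 < p < L:
            raise IndexError(f"permutation cut {p} must be internal (1..{L - 1})")
        child = r[p:] + r[:p]
    else:
        raise AssertionError(f"unhandled event type {t}")

    if new_id is None:
        new_id = f"{seq.id}.m{next(_clone_counter)}"
    return ProteinSequence(
        id=new_id, residues=child, generation=seq.generation + 1, parent_id=seq.id
    )


def make_founders(
    mode: str,
    length: int,
    n: int,
    rng: np.random.Generator,
    dictionary: EvolutionaryDictionary | None = None,
    seed_sequence: str | None = None,
    min_length: int = MIN_LENGTH,
) -> list[ProteinSequence]:
    """Build the generation-0 population.

    ``n_random``: n independent uniform random sequences of the given length.
    ``n_mutants_of_one``: one random (or supplied) seed, mutated n times
    independently — every founder differs from the seed by exactly one event.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    if length < min_length:
        raise ValueError(f"founder length {length} below minimum {min_length}")
    if mode == "n_random":
        return [
            ProteinSequence(id=f"f{i}", residues=random_residues(length, rng))
            for i in range(n)
        ]
    if mode == "n_mutants_of_one":
        dictionary = dictionary or EvolutionaryDictionary()
        seed = seed_sequence or random_residues(length, rng)
        base = ProteinSequence(id="seed", residues=seed)
        founders = []
        for i in range(n):
            ev = draw_mutation(base, dictionary, rng, min_length=min_length)
            child = apply_mutation(base, ev, new_id=f"f{i}")
            founders.append(
                ProteinSequence(id=f"f{i}", residues=child.residues, generation=0)
            )
        return founders
    raise ValueError(f"unknown founder mode {mode!r}")
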