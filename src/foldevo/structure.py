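"""Structure containers, the evaluator contract, and PDB I/O.

A :class:`StructureModel` holds, for one or two chains, backbone coordinates
(N, CA, C and a CB contact atom per residue; glycine uses its CA position as
the CB proxy), per-residue confidences (pLDDT, canonical [0, 1] scale) and a
global confidence (pTM).  Confidences are written to and read from the PDB
B-factor column on the conventional 0-100 scale; pTM travels in a
``REMARK 250`` line because PDB has no native slot for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

#: Atom order along axis 1 of ``StructureModel.coords``.
ATOM_ORDER = ("N", "CA", "C", "CB")

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}


@dataclass
class StructureModel:
    """Predicted backbone model for one or two chains.

    ``coords`` has shape (L, 4, 3) in Angstroms with atoms ordered as
    :data:`ATOM_ORDER`; ``plddt`` is per-residue confidence in [0, 1];
    ``ptm`` is the global confidence in [0, 1]; ``chain_of_residue`` labels
    each residue with its chain id.
    """

    sequence: str
    coords: np.ndarray
    plddt: np.ndarray
    ptm: float
    chain_of_residue: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        L = len(self.sequence)
        if self.chain_of_residue is None:
            self.chain_of_residue = np.array(["A"] * L)
        else:
            self.chain_of_residue = np.asarray(self.chain_of_residue)
        if self.coords.shape != (L, 4, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match sequence length {L}"
            )
        if self.plddt.shape != (L,):
            raise ValueError("plddt must have one entry per residue")
        if np.any(self.plddt < 0) or np.any(self.plddt > 1):
            raise ValueError("plddt entries must lie in [0, 1]")
        if not 0.0 <= self.ptm <= 1.0:
            raise ValueError("ptm must lie in [0, 1]")
        if len(self.chains) not in (1, 2):
            raise ValueError("a model carries one or two chains")

    # -- convenience views --------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_of_residue:
            seen.setdefault(str(c))
        return list(seen)

    def chain_mask(self, chain: str) -> np.ndarray:
        m = self.chain_of_residue == chain
        if not m.any():
            raise KeyError(f"no chain {chain!r} in model (have {self.chains})")
        return m

    def ca(self, chain: str | None = None) -> np.ndarray:
        c = self.coords[:, ATOM_ORDER.index("CA")]
        return c if chain is None else c[self.chain_mask(chain)]

    def cb(self, chain: str | None = None) -> np.ndarray:
        c = self.coords[:, ATOM_ORDER.index("CB")]
        return c if chain is None else c[self.chain_mask(chain)]

    def plddt_of(self, chain: str) -> np.ndarray:
        return self.plddt[self.chain_mask(chain)]

    def sequence_of(self, chain: str) -> str:
        m = self.chain_mask(chain)
        return "".join(a for a, keep in zip(self.sequence, m) if keep)

    @property
    def plddt_mean(self) -> float:
        return float(self.plddt.mean())


@runtime_checkable
class Evaluator(Protocol):
    """Contract every structure backend satisfies.

    ``deterministic`` declares whether identical inputs always yield
    identical models; ``batch_size`` is a throughput hint only — results
    must not depend on batching.
    """

    deterministic: bool
    batch_size: int

    def evaluate(self, sequences, partner: "StructureModel | None" = None) -> list:
        ...


class FixtureReplayEvaluator:
    """Replays pre-recorded models keyed by residue string.

    Lets the engine and tests run against any backend's stored output,
    proving the generation loop is backend-agnostic.
    """

    deterministic = True
    batch_size = 64

    def __init__(self, models: dict[str, StructureModel]):
        self._models = dict(models)

    def evaluate(self, sequences, partner=None) -> list[StructureModel]:
        out = []
        for s in sequences:
            key = s if isinstance(s, str) else s.residues
            try:
                out.append(self._models[key])
            except KeyError:
                raise KeyError(f"no recorded model for sequence {key[:20]}...") from None
        return out


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def write_structure(model: StructureModel, path) -> None:
    """Write a model as PDB; B-factors carry pLDDT x 100, pTM in REMARK 250."""
    L = model.n_residues
    glycine = np.array([a == "G" for a in model.sequence])
    n_atoms = 4 * L - int(glycine.sum())  # glycine rows drop the CB atom
    arr = struc.AtomArray(n_atoms)
    i = 0
    res_counter: dict[str, int] = {}
    for r in range(L):
        chain = str(model.chain_of_residue[r])
        res_counter[chain] = res_counter.get(chain, 0) + 1
        atoms = ("N", "CA", "C") if glycine[r] else ATOM_ORDER
        for name in atoms:
            arr.coord[i] = model.coords[r, ATOM_ORDER.index(name)]
            arr.chain_id[i] = chain
            arr.res_id[i] = res_counter[chain]
            arr.res_name[i] = _ONE_TO_THREE[model.sequence[r]]
            arr.atom_name[i] = name
            arr.element[i] = name[0]
            i += 1
    arr.set_annotation(
        "b_factor",
        np.repeat(
            np.round(model.plddt * 100.0, 2),
            [3 if g else 4 for g in glycine],
        ),
    )
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.lines.insert(0, f"REMARK 250 PTM {model.ptm:.4f}")
    pdb.write(str(path))


def read_structure(path) -> StructureModel:
    """Read a one- or two-chain PDB into a StructureModel.

    B-factors on the 0-100 scale are normalised to [0, 1].  Missing backbone
    atoms or unknown residue codes raise with the offending residue named.
    """
    pdb = PDBFile.read(str(path))
    ptm = 0.0
    for line in pdb.lines:
        if line.startswith("REMARK 250 PTM"):
            ptm = float(line.split()[-1])
    arr = pdb.get_structure(model=1, extra_fields=["b_factor"])

    seq_letters: list[str] = []
    coords: list[np.ndarray] = []
    plddt: list[float] = []
    chains: list[str] = []
    for chain_id in np.unique(arr.chain_id):
        sub = arr[arr.chain_id == chain_id]
        for res_id in np.unique(sub.res_id):
            res = sub[sub.res_id == res_id]
            res_name = str(res.res_name[0])
            if res_name not in _THREE_TO_ONE:
                raise ValueError(f"unknown residue code {res_name} at {chain_id}{res_id}")
            one = _THREE_TO_ONE[res_name]
            atom_xyz = {}
            for name in ATOM_ORDER:
                hit = res[res.atom_name == name]
                if len(hit) == 0:
                    if name == "CB" and one == "G":
                        continue
                    raise ValueError(
                        f"residue {res_name} {chain_id}{res_id} is missing atom {name}"
                    )
                atom_xyz[name] = hit.coord[0]
            if "CB" not in atom_xyz:
                atom_xyz["CB"] = atom_xyz["CA"]  # glycine proxy
            coords.append(np.stack([atom_xyz[n] for n in ATOM_ORDER]))
            seq_letters.append(one)
            b = float(res.b_factor[res.atom_name == "CA"][0])
            plddt.append(b / 100.0)
            chains.append(str(chain_id))

    return StructureModel(
        sequence="".join(seq_letters),
        coords=np.stack(coords),
        plddt=np.clip(np.array(plddt), 0.0, 1.0),
        ptm=ptm,
        chain_of_residue=np.array(chains),
    )


def concatenate_models(
    a: StructureModel, b: StructureModel, chain_a: str = "A", chain_b: str = "B"
) -> StructureModel:
    """Join two single-chain models into one two-chain complex model."""
    return StructureModel(
        sequence=a.sequence + b.sequence,
        coords=np.concatenate([a.coords, b.coords]),
        plddt=np.concatenate([a.plddt, b.plddt]),
        ptm=a.ptm,
        chain_of_residue=np.array([chain_a] * a.n_residues + [chain_b] * b.n_residues),
    )
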