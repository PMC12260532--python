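"""Secondary-structure assignment from backbone geometry.

The default assigner classifies residues from the CA trace alone, using
virtual-bond distance windows in the spirit of P-SEA: d13 (CA_i to CA_{i+2})
and d14 (CA_i to CA_{i+3}) fall in narrow, well-separated bands for ideal
alpha-helices (~5.4 / ~5.1 A) and extended strands (~6.6 / ~10 A).  The
assigner is pluggable — anything mapping a StructureModel to an H/E/C string
per chain can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import StructureModel


@dataclass(frozen=True)
class SecondaryStructureAnnotation:
    """Per-residue H/E/C labels and the maximal same-label elements."""

    labels: str
    #: list of (label, start, end) with end exclusive; elements tile the chain
    elements: tuple[tuple[str, int, int], ...]

    @property
    def helix_lengths(self) -> list[int]:
        return [e - s for lab, s, e in self.elements if lab == "H"]

    @property
    def strand_lengths(self) -> list[int]:
        return [e - s for lab, s, e in self.elements if lab == "E"]

    def composition(self) -> dict[str, float]:
        L = len(self.labels)
        return {c: self.labels.count(c) / L for c in "HEC"}


def elements_from_labels(labels: str) -> tuple[tuple[str, int, int], ...]:
    out = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        out.append((labels[i], i, j))
        i = j
    return tuple(out)


# distance windows (A) for helix and strand candidates
_H_D13 = (5.0, 5.8)
_H_D14 = (4.6, 5.6)
_E_D13 = (6.3, 7.2)
_E_D14 = (9.0, 10.7)


def labels_from_ca(ca: np.ndarray) -> str:
    """H/E/C labels for one chain's CA trace; chains under 4 residues are coil."""
    L = len(ca)
    if L < 4:
        return "C" * L
    d13 = np.linalg.norm(ca[2:] - ca[:-2], axis=1)  # index i -> CA_i..CA_{i+2}
    d14 = np.linalg.norm(ca[3:] - ca[:-3], axis=1)
    labels = np.full(L, "C")

    def in_band(x, band):
        return (band[0] < x) & (x < band[1])

    h13 = in_band(d13, _H_D13)
    h14 = in_band(d14, _H_D14)
    e13 = in_band(d13, _E_D13)
    e14 = in_band(d14, _E_D14)
    # two consecutive d13 hits plus a d14 hit anchor four residues; helix wins
    for i in range(L - 3):
        if e13[i] and e13[i + 1] and e14[i]:
            labels[i : i + 4] = "E"
    for i in range(L - 3):
        if h13[i] and h13[i + 1] and h14[i]:
            labels[i : i + 4] = "H"
    return "".join(labels)


def assign_secondary_structure(
    model: StructureModel, chain: str | None = None, assigner=None
) -> SecondaryStructureAnnotation:
    """Annotate one chain of a model (default: the first chain).

    ``assigner`` may override the geometric default; it receives the (n, 3)
    CA coordinate array and must return an H/E/C string.
    """
    chain = chain or model.chains[0]
    ca = model.ca(chain)
    labels = (assigner or labels_from_ca)(ca)
    if len(labels) != len(ca):
        raise ValueError("assigner returned wrong number of labels")
    return SecondaryStructureAnnotation(
        labels=labels, elements=elements_from_labels(labels)
    )
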