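"""Composite structure-based fitness.

The score of an individual is the product

    s = <pLDDT> * pTM * CD * (ipLDDT * iCD) * constr

where CD is the long-range C-beta contact density (contacts with sequence
separation > 5, CB-CB distance < 6 A and both residues confident, per
residue), ipLDDT/iCD are the interface analogues for a two-chain complex
(identity 1 for monomers), and ``constr`` is a product of logistic length
penalties on the whole chain and on each helix/strand element.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import expit

from .secondary import SecondaryStructureAnnotation, assign_secondary_structure
from .structure import StructureModel

#: CB-CB contact distance cutoff (A)
CONTACT_CUTOFF = 6.0
#: minimum sequence separation for intra-chain contacts (strict >)
MIN_SEPARATION = 5
#: per-residue confidence floor for a contact (strict >, [0,1] scale)
PLDDT_FLOOR = 0.5


@dataclass(frozen=True)
class SigmoidLaw:
    """Logistic length penalty P(L) = 1 - 1/(1 + e^{C (L0 - L)}).

    Strictly decreasing in L with P(L0) = 0.5: a chain or element at the
    midpoint length halves the score; well under it the factor is ~1.
    """

    steepness: float
    midpoint: float

    def __call__(self, length: float) -> float:
        return float(expit(self.steepness * (self.midpoint - length)))


@dataclass(frozen=True)
class ConstraintParams:
    """Length laws for the whole protein and for helix/strand elements."""

    protein: SigmoidLaw = SigmoidLaw(steepness=0.2, midpoint=250)
    helix: SigmoidLaw = SigmoidLaw(steepness=0.5, midpoint=30)
    strand: SigmoidLaw = SigmoidLaw(steepness=0.5, midpoint=12)


DEFAULT_CONSTRAINTS = ConstraintParams()


@dataclass(frozen=True)
class FitnessBreakdown:
    """All multiplicative terms plus the composite score."""

    plddt_mean: float
    ptm: float
    cd: float
    iplddt: float
    icd: float
    constr: float
    score: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def contact_density(model: StructureModel, chain: str | None = None) -> float:
    """Long-range contacts per residue for one chain.

    Counts unordered residue pairs with |i - j| > 5, CB-CB distance < 6 A,
    and pLDDT > 0.5 on both residues, normalised by chain length.
    """
    chain = chain or model.chains[0]
    mask = model.chain_mask(chain)
    cb = model.coords[mask][:, 3]
    plddt = model.plddt[mask]
    n = len(cb)
    if n == 0:
        raise ValueError("empty chain")
    d = cdist(cb, cb)
    i, j = np.triu_indices(n, k=MIN_SEPARATION + 1)
    ok = (
        (d[i, j] < CONTACT_CUTOFF)
        & (plddt[i] > PLDDT_FLOOR)
        & (plddt[j] > PLDDT_FLOOR)
    )
    return float(ok.sum()) / n


def interface_terms(
    model: StructureModel, evolving_chain: str = "A"
) -> tuple[float, float]:
    """(ipLDDT, iCD) for a two-chain complex.

    Qualifying inter-chain pairs: CB-CB distance < 6 A, both residues with
    pLDDT > 0.5 (no sequence-separation filter across chains).  ipLDDT is
    the mean pLDDT over residues of either chain in at least one qualifying
    pair (0 if the interface is empty); iCD is the number of qualifying
    pairs per evolving-chain residue.
    """
    chains = model.chains
    if len(chains) != 2:
        raise ValueError("interface terms require a two-chain model")
    other = [c for c in chains if c != evolving_chain][0]
    m_a = model.chain_mask(evolving_chain)
    m_b = model.chain_mask(other)
    cb_a, cb_b = model.coords[m_a][:, 3], model.coords[m_b][:, 3]
    p_a, p_b = model.plddt[m_a], model.plddt[m_b]
    d = cdist(cb_a, cb_b)
    ok = (d < CONTACT_CUTOFF) & (p_a[:, None] > PLDDT_FLOOR) & (p_b[None, :] > PLDDT_FLOOR)
    n_contacts = int(ok.sum())
    icd = n_contacts / len(cb_a)
    if n_contacts == 0:
        return 0.0, 0.0
    iface_p = np.concatenate([p_a[ok.any(axis=1)], p_b[ok.any(axis=0)]])
    return float(iface_p.mean()), float(icd)


def constraint_factor(
    seq_len: int,
    ss: SecondaryStructureAnnotation,
    params: ConstraintParams = DEFAULT_CONSTRAINTS,
) -> float:
    """Whole-chain length penalty times per-element helix/strand penalties."""
    f = params.protein(seq_len)
    for L in ss.helix_lengths:
        f *= params.helix(L)
    for L in ss.strand_lengths:
        f *= params.strand(L)
    return f


def fitness_score(
    seq,
    model: StructureModel,
    params: ConstraintParams | None = DEFAULT_CONSTRAINTS,
    evolving_chain: str = "A",
    ss: SecondaryStructureAnnotation | None = None,
) -> FitnessBreakdown:
    """Score one individual from its structure model.

    ``seq`` may be a ProteinSequence or a residue string; it must match the
    evolving chain of the model.  Monomers take identity interface terms.
    Passing ``params=None`` disables the length constraints (constr = 1).
    """
    residues = seq if isinstance(seq, str) else seq.residues
    chain_seq = model.sequence_of(evolving_chain)
    if residues != chain_seq:
        raise ValueError(
            f"sequence (len {len(residues)}) does not match model chain "
            f"{evolving_chain} (len {len(chain_seq)})"
        )
    mask = model.chain_mask(evolving_chain)
    plddt_mean = float(model.plddt[mask].mean())
    cd = contact_density(model, evolving_chain)
    if len(model.chains) == 2:
        iplddt, icd = interface_terms(model, evolving_chain)
    else:
        iplddt = icd = 1.0
    if params is None:
        constr = 1.0
    else:
        annotation = ss or assign_secondary_structure(model, evolving_chain)
        constr = constraint_factor(len(residues), annotation, params)
    score = plddt_mean * model.ptm * cd * iplddt * icd * constr
    return FitnessBreakdown(
        plddt_mean=plddt_mean,
        ptm=model.ptm,
        cd=cd,
        iplddt=iplddt,
        icd=icd,
        constr=constr,
        score=score,
    )
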