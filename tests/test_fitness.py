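"""Contact density, interface terms, length constraints and the composite score."""

import numpy as np
import pytest
from scipy.special import expit

from foldevo import (
    ConstraintParams,
    SigmoidLaw,
    constraint_factor,
    contact_density,
    fitness_score,
    interface_terms,
)
from foldevo.secondary import elements_from_labels, labels_from_ca
from foldevo.secondary import SecondaryStructureAnnotation
from foldevo.sequences import random_residues
from foldevo.surrogate import DEFAULT_PARAMS, _ideal_helix, _ideal_strand

from conftest import make_model


def annotation(labels: str) -> SecondaryStructureAnnotation:
    return SecondaryStructureAnnotation(labels, elements_from_labels(labels))


def brute_force_cd(cb, plddt, length):
    count = 0
    for i in range(len(cb)):
        for j in range(i + 1, len(cb)):
            if (
                j - i > 5
                and np.linalg.norm(cb[i] - cb[j]) < 6.0
                and plddt[i] > 0.5
                and plddt[j] > 0.5
            ):
                count += 1
    return count / length


# -- contact density ---------------------------------------------------------


def test_short_chain_has_no_contacts(rng):
    model = make_model(rng.normal(scale=1.0, size=(6, 3)), plddt=0.9)
    assert contact_density(model) == 0.0


def test_low_confidence_residues_never_contact(rng):
    cb = rng.normal(scale=2.0, size=(30, 3))  # dense cloud, many close pairs
    model = make_model(cb, plddt=0.4)
    assert contact_density(model) == 0.0


def test_contact_density_matches_exhaustive_scan(rng):
    for _ in range(200):
        n = int(rng.integers(7, 81))
        cb = rng.uniform(0, n ** (1 / 3) * 4.5, size=(n, 3))
        plddt = rng.uniform(0, 1, size=n)
        model = make_model(cb, plddt)
        assert contact_density(model) == pytest.approx(
            brute_force_cd(cb, plddt, n), abs=0
        )


# -- interface terms ---------------------------------------------------------


def two_chain_model(cb_a, cb_b, plddt_a, plddt_b):
    cb = np.concatenate([cb_a, cb_b])
    plddt = np.concatenate(
        [np.broadcast_to(plddt_a, (len(cb_a),)), np.broadcast_to(plddt_b, (len(cb_b),))]
    )
    chain = np.array(["A"] * len(cb_a) + ["B"] * len(cb_b))
    return make_model(cb, plddt, chain=chain)


def test_distant_chains_have_empty_interface(rng):
    a = rng.normal(size=(10, 3))
    b = rng.normal(size=(8, 3)) + 100.0
    iplddt, icd = interface_terms(two_chain_model(a, b, 0.9, 0.9))
    assert (iplddt, icd) == (0.0, 0.0)


def test_single_interface_pair_counts_per_evolving_residue():
    a = np.array([[i * 50.0, 0, 0] for i in range(25)])
    b = np.array([[3.0, 0, 0], [500.0, 500, 500]])  # one CB within 6 A of a[0]
    iplddt, icd = interface_terms(two_chain_model(a, b, 0.8, 0.9))
    assert icd == pytest.approx(1 / 25)
    assert iplddt == pytest.approx((0.8 + 0.9) / 2)


def test_interface_terms_match_exhaustive_scan(rng):
    for _ in range(100):
        na, nb = int(rng.integers(5, 40)), int(rng.integers(5, 40))
        a = rng.uniform(0, 15, size=(na, 3))
        b = rng.uniform(0, 15, size=(nb, 3))
        pa = rng.uniform(0, 1, size=na)
        pb = rng.uniform(0, 1, size=nb)
        model = two_chain_model(a, b, pa, pb)
        count = 0
        touched_a, touched_b = set(), set()
        for i in range(na):
            for j in range(nb):
                if np.linalg.norm(a[i] - b[j]) < 6.0 and pa[i] > 0.5 and pb[j] > 0.5:
                    count += 1
                    touched_a.add(i)
                    touched_b.add(j)
        iplddt, icd = interface_terms(model)
        assert icd == pytest.approx(count / na, abs=0)
        if count:
            expected = np.concatenate(
                [pa[sorted(touched_a)], pb[sorted(touched_b)]]
            ).mean()
            assert iplddt == pytest.approx(expected)
        else:
            assert iplddt == 0.0


def test_monomer_rejected_by_interface_terms(rng):
    with pytest.raises(ValueError):
        interface_terms(make_model(rng.normal(size=(10, 3)), 0.9))


# -- constraint sigmoids -----------------------------------------------------


def test_sigmoid_halves_score_at_midpoint():
    assert constraint_factor(250, annotation("C" * 250)) == 0.5


def test_sigmoid_saturates_for_short_chains():
    assert constraint_factor(50, annotation("C" * 50)) == pytest.approx(1.0, abs=1e-15)


def test_helix_element_penalty_closed_form():
    labels = "H" * 36 + "C" * 4
    expected = expit(0.2 * (250 - 40)) * expit(0.5 * (30 - 36))
    assert constraint_factor(40, annotation(labels)) == pytest.approx(expected)
    assert expit(0.5 * (30 - 36)) == pytest.approx(0.04742587, abs=1e-8)


@pytest.mark.parametrize(
    "law", [SigmoidLaw(0.2, 250), SigmoidLaw(0.5, 30), SigmoidLaw(0.5, 12)]
)
def test_sigmoid_laws_decreasing_and_symmetric(law):
    grid = np.arange(1, 2 * law.midpoint)
    values = np.array([law(x) for x in grid])
    diffs = np.diff(values)
    assert np.all(diffs <= 0)
    # strictly decreasing wherever float precision has not saturated to 0 or 1
    interior = (values > 1e-12) & (values < 1 - 1e-12)
    assert np.all(diffs[interior[:-1] & interior[1:]] < 0)
    assert law(law.midpoint) == 0.5
    for x in (1, 3, 7, 11):
        assert law(law.midpoint - x) + law(law.midpoint + x) == pytest.approx(1.0)


def test_multiple_elements_multiply():
    labels = "H" * 10 + "C" * 3 + "E" * 5 + "C" * 2
    L = len(labels)
    params = ConstraintParams()
    expected = params.protein(L) * params.helix(10) * params.strand(5)
    assert constraint_factor(L, annotation(labels), params) == pytest.approx(expected)


# -- geometric secondary-structure assignment --------------------------------


def test_ideal_helix_is_labelled_helix():
    labels = labels_from_ca(_ideal_helix(20, DEFAULT_PARAMS))
    assert labels.count("H") >= 18


def test_ideal_strand_is_labelled_strand():
    labels = labels_from_ca(_ideal_strand(10, DEFAULT_PARAMS))
    assert labels.count("E") >= 8


def test_random_coil_is_mostly_coil(surrogate):
    # an all-polar scrambled sequence folds as a random walk in the surrogate
    model = surrogate.evaluate(["DSGNDSTKNDGSTNKDGNSTDKGN"])[0]
    labels = labels_from_ca(model.ca("A"))
    assert labels.count("C") / len(labels) >= 0.8


def test_chains_shorter_than_four_are_coil():
    assert labels_from_ca(_ideal_helix(3, DEFAULT_PARAMS)) == "CCC"


def test_assigner_agrees_with_independent_psea_on_ideal_helix():
    import biotite.structure as struc

    ca = _ideal_helix(20, DEFAULT_PARAMS)
    arr = struc.AtomArray(20)
    arr.coord = ca.astype(np.float32)
    arr.chain_id[:] = "A"
    arr.res_id[:] = np.arange(1, 21)
    arr.res_name[:] = "ALA"
    arr.atom_name[:] = "CA"
    arr.element[:] = "C"
    reference = "".join(struc.annotate_sse(arr))
    ours = labels_from_ca(ca)
    interior = slice(2, 18)
    agreement = np.mean(
        [a == ("H" if b == "a" else "E" if b == "b" else "C")
         for a, b in zip(ours[interior], reference[interior])]
    )
    assert agreement >= 0.9


# -- composite score ---------------------------------------------------------


def test_score_is_product_of_terms_hand_built():
    # 14 residues on a line, except residues 0 and 13 brought within 6 A
    cb = np.array([[i * 50.0, 0, 0] for i in range(14)])
    cb[13] = [4.0, 0, 0]
    model = make_model(cb, plddt=0.8, ptm=0.7)
    b = fitness_score(model.sequence, model, params=None)
    assert b.cd == pytest.approx(1 / 14)
    assert (b.iplddt, b.icd, b.constr) == (1.0, 1.0, 1.0)
    assert b.score == pytest.approx(0.8 * 0.7 * (1 / 14))


def test_zero_contact_density_zeroes_the_score(rng):
    cb = np.array([[i * 50.0, 0, 0] for i in range(12)])
    model = make_model(cb, plddt=0.95, ptm=0.9)
    b = fitness_score(model.sequence, model, params=None)
    assert b.cd == 0.0 and b.score == 0.0


def test_breakdown_remultiplies_to_score(surrogate, rng):
    for _ in range(200):
        model = surrogate.evaluate([random_residues(int(rng.integers(12, 60)), rng)])[0]
        b = fitness_score(model.sequence, model)
        assert b.score == b.plddt_mean * b.ptm * b.cd * b.iplddt * b.icd * b.constr
        assert b.score >= 0.0


def test_length_mismatch_is_an_error(surrogate, rng):
    model = surrogate.evaluate([random_residues(20, rng)])[0]
    with pytest.raises(ValueError):
        fitness_score("A" * 19, model)
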