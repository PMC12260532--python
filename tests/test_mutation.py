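"""Mutation operators: event algebra, rate convergence, founder construction."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from foldevo import (
    AMINO_ACIDS,
    EvolutionaryDictionary,
    MutationEvent,
    MutationType,
    ProteinSequence,
    apply_mutation,
    draw_mutation,
    make_founders,
)
from foldevo.mutation import MatrixSubstitution, FrequencySubstitution


def seq(residues, sid="s"):
    return ProteinSequence(id=sid, residues=residues)


@pytest.mark.parametrize(
    "residues, event, expected",
    [
        ("ACDEFG", MutationEvent(MutationType.CIRCULAR_PERMUTATION, position=2), "DEFGAC"),
        ("MKV", MutationEvent(MutationType.COMPLETE_DUPLICATION), "MKVMKV"),
        ("MKVW", MutationEvent(MutationType.SUBSTITUTION, position=1, payload="A"), "MAVW"),
        ("MKVW", MutationEvent(MutationType.SINGLE_INSERTION, position=2, payload="G"), "MKGVW"),
        ("MKVW", MutationEvent(MutationType.SINGLE_DELETION, position=0), "KVW"),
        ("MKVWAC", MutationEvent(MutationType.MULTI_DELETION, position=1, end=4), "MAC"),
        ("MKVWAC", MutationEvent(MutationType.RANDOM_INSERTION, position=6, payload="GG"), "MKVWACGG"),
        ("MKVWAC", MutationEvent(MutationType.PARTIAL_DUPLICATION, position=1, end=3), "MKVKVWAC"),
    ],
)
def test_apply_mutation_examples(residues, event, expected):
    child = apply_mutation(seq(residues), event)
    assert child.residues == expected
    assert child.parent_id == "s"
    assert child.generation == 1


def test_apply_mutation_rejects_out_of_range():
    with pytest.raises(IndexError):
        apply_mutation(seq("MKVW"), MutationEvent(MutationType.SUBSTITUTION, position=9, payload="A"))
    with pytest.raises(IndexError):
        apply_mutation(seq("MKVW"), MutationEvent(MutationType.CIRCULAR_PERMUTATION, position=0))


def test_degenerate_rate_table_always_substitutes(rng):
    d = EvolutionaryDictionary(event_rates={MutationType.SUBSTITUTION: 1.0})
    s = seq("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(50):
        ev = draw_mutation(s, d, rng)
        assert ev.type is MutationType.SUBSTITUTION
        assert s.residues[ev.position] != ev.payload  # never a self-replacement


def test_minimum_length_floor_coerces_deletion_to_substitution(rng):
    d = EvolutionaryDictionary(event_rates={MutationType.SINGLE_DELETION: 1.0})
    s = seq("ACDEFGHIKL")  # exactly the minimum length of 10
    for _ in range(20):
        assert draw_mutation(s, d, rng).type is MutationType.SUBSTITUTION


def test_maximum_length_ceiling_coerces_duplication(rng):
    d = EvolutionaryDictionary(event_rates={MutationType.COMPLETE_DUPLICATION: 1.0})
    s = seq("A" * 300)  # doubling would exceed the 500-residue cap
    assert draw_mutation(s, d, rng).type is MutationType.SUBSTITUTION


def test_event_frequencies_converge_to_rates(rng):
    rates = {
        MutationType.SUBSTITUTION: 0.9,
        MutationType.SINGLE_INSERTION: 0.05,
        MutationType.SINGLE_DELETION: 0.05,
    }
    d = EvolutionaryDictionary(event_rates=rates)
    s = seq("ACDEFGHIKLMNPQRSTVWY" * 3)
    n = 100_000
    counts = Counter(draw_mutation(s, d, rng).type for _ in range(n))
    for ev_type, p in rates.items():
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(counts[ev_type] - n * p) < 3 * sigma


def test_matrix_substitution_matches_row_distribution(rng):
    # random row-stochastic replacement table
    raw = rng.uniform(size=(20, 20))
    model = MatrixSubstitution(raw)
    original = "L"
    row = model.row(original)
    assert row[AMINO_ACIDS.index("L")] == 0.0
    n = 100_000
    draws = Counter(model.draw(original, rng) for _ in range(n))
    observed = np.array([draws[a] for a in AMINO_ACIDS if a != original])
    expected = np.array([row[i] for i, a in enumerate(AMINO_ACIDS) if a != original]) * n
    chi2 = stats.chisquare(observed, expected)
    assert chi2.pvalue > 0.001


def test_frequency_substitution_never_returns_original(rng):
    freqs = {a: (i + 1.0) for i, a in enumerate(AMINO_ACIDS)}
    model = FrequencySubstitution(freqs)
    assert all(model.draw("W", rng) != "W" for _ in range(200))


def test_rates_must_sum_to_one():
    with pytest.raises(ValueError):
        EvolutionaryDictionary(event_rates={MutationType.SUBSTITUTION: 0.7})


def test_dictionary_yaml_roundtrip(tmp_path):
    d = EvolutionaryDictionary()
    d.to_yaml(tmp_path / "dict.yaml")
    d2 = EvolutionaryDictionary.from_file(tmp_path / "dict.yaml")
    assert d2.event_rates == d.event_rates
    assert d2.indel_length_law == d.indel_length_law


def test_matrix_table_parser(tmp_path, rng):
    raw = rng.uniform(0.1, 1.0, size=(20, 20))
    header = " ".join(AMINO_ACIDS)
    rows = [
        f"{a} " + " ".join(f"{x:.6f}" for x in raw[i])
        for i, a in enumerate(AMINO_ACIDS)
    ]
    path = tmp_path / "matrix.txt"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    model = MatrixSubstitution.from_table(path)
    np.testing.assert_allclose(model.matrix.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(np.diag(model.matrix) == 0.0)


# -- length algebra and composition properties ------------------------------

_EXPECTED_DELTA = {
    MutationType.SUBSTITUTION: lambda L, ev: 0,
    MutationType.SINGLE_INSERTION: lambda L, ev: 1,
    MutationType.SINGLE_DELETION: lambda L, ev: -1,
    MutationType.MULTI_DELETION: lambda L, ev: -(ev.end - ev.position),
    MutationType.RANDOM_INSERTION: lambda L, ev: len(ev.payload),
    MutationType.PARTIAL_DUPLICATION: lambda L, ev: ev.end - ev.position,
    MutationType.COMPLETE_DUPLICATION: lambda L, ev: L,
    MutationType.CIRCULAR_PERMUTATION: lambda L, ev: 0,
}


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_length_algebra_over_random_events(seed):
    rng = np.random.default_rng(seed)
    d = EvolutionaryDictionary()
    from foldevo.sequences import random_residues

    s = seq(random_residues(int(rng.integers(10, 80)), rng))
    for _ in range(20):
        ev = draw_mutation(s, d, rng)
        child = apply_mutation(s, ev)
        assert len(child) - len(s) == _EXPECTED_DELTA[ev.type](len(s), ev)
        s = child


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=60),
    st.integers(1, 1000),
)
def test_circular_permutation_is_a_rotation(residues, raw_cut):
    cut = 1 + raw_cut % (len(residues) - 1) if len(residues) > 1 else 1
    child = apply_mutation(
        seq(residues), MutationEvent(MutationType.CIRCULAR_PERMUTATION, position=cut)
    )
    # multiset conserved and both fragments appear in original order
    assert sorted(child.residues) == sorted(residues)
    assert child.residues == residues[cut:] + residues[:cut]
    assert child.residues in (residues + residues)


# -- founders ----------------------------------------------------------------


def test_n_random_founders_have_requested_shape(rng):
    founders = make_founders("n_random", length=24, n=100, rng=rng)
    assert len(founders) == 100
    assert all(len(f) == 24 and f.generation == 0 for f in founders)
    assert len({f.id for f in founders}) == 100


def test_mutant_founders_are_one_substitution_from_seed(rng):
    d = EvolutionaryDictionary(event_rates={MutationType.SUBSTITUTION: 1.0})
    from foldevo.sequences import random_residues

    base = random_residues(30, rng)
    founders = make_founders(
        "n_mutants_of_one", length=30, n=20, rng=rng, dictionary=d, seed_sequence=base
    )
    for f in founders:
        hamming = sum(a != b for a, b in zip(f.residues, base))
        assert hamming == 1


def test_founders_reproducible_from_seed():
    a = make_founders("n_random", 24, 10, np.random.default_rng(5))
    b = make_founders("n_random", 24, 10, np.random.default_rng(5))
    assert [f.residues for f in a] == [f.residues for f in b]


def test_founder_preconditions():
    with pytest.raises(ValueError):
        make_founders("n_random", 24, 1, np.random.default_rng(0))
    with pytest.raises(ValueError):
        make_founders("n_random", 5, 10, np.random.default_rng(0))
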