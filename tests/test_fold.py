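"""Folding dynamic programs against the exhaustive enumeration oracle."""

import math
import random

import numpy as np
import pytest

from m6afold.constants import RT37
from m6afold.energy import structure_energy, ENSEMBLE_OPTIONS
from m6afold.fold import (buried_probability, enumerate_structures, mfe_fold,
                          opening_cost, partition, window_bounds,
                          window_profile)
from m6afold.structure import SecondaryStructure, StructureError

MALAT1 = "AACUUAAUGUUUUUGCAUUGGACUUUGAGUUA"
MALAT1_M = MALAT1[:21] + "6" + MALAT1[22:]


def _ensemble_reference(params, seq):
    """Boltzmann statistics over the enumerated ensemble."""
    structs = list(enumerate_structures(params, seq))
    n = len(seq)
    z = 0.0
    pp = np.zeros((n + 1, n + 1))
    bur = np.zeros(n + 1)
    for st, e in structs:
        w = math.exp(-e / RT37)
        z += w
        for (i, j) in st.pairs:
            pp[i, j] += w
            if i > 1 and j < n and (i - 1, j + 1) in st.pairs \
                    and (i + 1, j - 1) in st.pairs:
                bur[i] += w
                bur[j] += w
    return structs, z, pp / z, bur / z


def test_unpairable_sequence_trivial(rna):
    res = mfe_fold(rna, "CCCCCCCCCC")
    assert res.structure.pairs == frozenset()
    assert res.dg37 == 0.0
    pr = partition(rna, "CCCCCCCCCC")
    assert pr.Q == pytest.approx(1.0)
    assert np.all(pr.pairprob == 0.0)
    assert np.all(pr.buried == 0.0)


def test_enumeration_single_structure_when_unpairable(rna):
    structs = list(enumerate_structures(rna, "AAACCCA"))
    assert len(structs) == 1
    assert structs[0][0].pairs == frozenset()


def test_enumeration_count_matches_independent_recursion(rna):
    seq = "GGGAAACCC"

    def count(i, j, can):
        if i >= j:
            return 1
        total = count(i + 1, j, can)
        for k in range(i + 4, j + 1):
            if can(i, k):
                total += count(i + 1, k - 1, can) * count(k + 1, j, can)
        return total

    can = lambda i, k: rna.alphabet.can_pair(seq[i - 1], seq[k - 1])
    expected = count(1, len(seq), can)
    assert len(list(enumerate_structures(rna, seq))) == expected


def test_enumeration_guard():
    from m6afold.params import load_rna_params
    with pytest.raises(ValueError, match="limited"):
        list(enumerate_structures(load_rna_params(), "A" * 30))


@pytest.mark.parametrize("seed", range(6))
def test_dp_matches_enumeration(rna, m6a, seed):
    rng = random.Random(seed)
    params = m6a if seed % 2 else rna
    alpha = "ACGU6" if seed % 2 else "ACGU"
    seq = "".join(rng.choice(alpha) for _ in range(rng.randint(11, 15)))
    structs, z, pp, bur = _ensemble_reference(params, seq)
    emin = min(e for _, e in structs)
    res = mfe_fold(params, seq)
    assert res.dg37 == pytest.approx(emin, abs=1e-9)
    assert structure_energy(params, seq, res.structure,
                            ENSEMBLE_OPTIONS) == pytest.approx(res.dg37)
    pr = partition(params, seq)
    assert pr.Q == pytest.approx(z, rel=1e-9)
    assert np.allclose(np.triu(pp), np.triu(pr.pairprob), atol=1e-9)
    assert np.allclose(bur, pr.buried, atol=1e-9)


def test_partition_invariants(rna):
    seq = "GGCAGCAAAAGCUGCC"
    pr = partition(rna, seq)
    res = mfe_fold(rna, seq)
    n = pr.N
    assert pr.Q >= math.exp(-res.dg37 / RT37)
    floor = math.exp(-res.dg37 / RT37) / pr.Q
    for (i, j) in res.structure.pairs:
        assert pr.pairprob[i, j] >= floor - 1e-12
    # per-nucleotide pairing probability bounds the buried probability
    colsum = pr.pairprob.sum(axis=0)
    for i in range(1, n + 1):
        assert colsum[i] <= 1.0 + 1e-9
        assert pr.buried[i] <= colsum[i] + 1e-12
    assert pr.buried[1] == 0.0 and pr.buried[n] == 0.0
    expected_pairs = np.triu(pr.pairprob).sum()
    assert pr.buried.sum() <= 2 * expected_pairs + 1e-9


def test_buried_first_last_zero_everywhere(rna):
    rng = random.Random(3)
    for _ in range(3):
        seq = "".join(rng.choice("ACGU") for _ in range(12))
        prof = buried_probability(rna, seq)
        assert prof[0] == 0.0 and prof[-1] == 0.0


def test_m6a_free_folding_identical_between_sets(rna, m6a):
    seq = "GGACUAGUCCAAGG"
    ra, rm = mfe_fold(rna, seq), mfe_fold(m6a, seq)
    assert ra.structure.pairs == rm.structure.pairs
    assert ra.dg37 == pytest.approx(rm.dg37)
    pa, pm = partition(rna, seq), partition(m6a, seq)
    assert pa.Q == pytest.approx(pm.Q, rel=1e-12)
    assert np.allclose(pa.buried, pm.buried)


# ----------------------------------------------------------------------
# the MALAT1 stem-loop

def test_malat1_closed_conformation_with_and_without_methylation(rna, m6a):
    ra = mfe_fold(rna, MALAT1)
    rm = mfe_fold(m6a, MALAT1_M)
    assert ra.structure.pairs == rm.structure.pairs
    # the protein-binding site around the five Us is sequestered in a stem
    assert {(10, 22), (11, 21), (12, 20)} <= ra.structure.pairs


def test_opening_cost_identity_and_definition(rna):
    closed = mfe_fold(rna, MALAT1).structure
    assert opening_cost(rna, MALAT1, closed, closed) == 0.0
    open_ = SecondaryStructure(
        32, closed.pairs - {(10, 22), (11, 21), (12, 20)})
    cost = opening_cost(rna, MALAT1, closed, open_)
    assert cost == pytest.approx(
        structure_energy(rna, MALAT1, open_)
        - structure_energy(rna, MALAT1, closed))
    pt = open_.partner()
    assert all(pt[x] == 0 for x in range(10, 15))


def test_opening_requires_substructure(rna):
    closed = mfe_fold(rna, MALAT1).structure
    other = SecondaryStructure(32, [(1, 30)])
    with pytest.raises(StructureError, match="sub-structure"):
        opening_cost(rna, MALAT1, closed, other)


# ----------------------------------------------------------------------
# windows

def test_window_bounds_arithmetic():
    assert window_bounds(100, 50, 800) == (1, 100)
    assert window_bounds(4000, 2000, 800) == (1600, 2399)
    start, end = window_bounds(4000, 2000, 800)
    assert 2000 - start + 1 == 401
    assert window_bounds(4000, 100, 800) == (1, 800)
    assert window_bounds(4000, 3950, 800) == (3201, 4000)
    with pytest.raises(ValueError):
        window_bounds(0, 1, 800)
    with pytest.raises(ValueError):
        window_bounds(10, 11, 800)


def test_window_profile_on_consensus_site(rna, m6a):
    from m6afold.synth import consensus_site_sequences
    seq, site = consensus_site_sequences(seed=4, n=1)[0]
    met = seq[:site - 1] + "6" + seq[site:]
    wa = window_profile(rna, seq, site, window=40)
    wm = window_profile(m6a, met, site, window=40)
    pa = wa.buried[wa.site_offset - 1]
    pm = wm.buried[wm.site_offset - 1]
    assert np.isfinite(pa) and np.isfinite(pm)
    assert pa != pytest.approx(pm)
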