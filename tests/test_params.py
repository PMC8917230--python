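"""Parameter tables: dialect round-trip, m6A construction rules,
strand-reversal symmetries."""

import math
from pathlib import Path

import pytest

from m6afold.params import (MeasuredMotif, ParameterError, build_m6a_tables,
                            canonical_stack, load_m6a_params, load_rna_params,
                            m6a_stack_contexts, read_parameter_set,
                            write_parameter_set)


def test_roundtrip_rna(rna, tmp_path):
    write_parameter_set(rna, tmp_path)
    back = read_parameter_set(tmp_path, rna.alphabet)
    for name in ("stack", "dangle5", "dangle3", "tstack", "tstackh",
                 "tstacki", "tstacki1n", "tstacki23", "tstackm", "int11",
                 "int21", "int22", "hairpin_init", "bulge_init",
                 "internal_init", "special_hairpins", "end_penalty"):
        assert getattr(back, name) == getattr(rna, name), name
    assert back.duplex_init == rna.duplex_init
    assert back.symmetry_corr == rna.symmetry_corr


def test_roundtrip_m6a(m6a, tmp_path):
    write_parameter_set(m6a, tmp_path)
    back = read_parameter_set(tmp_path, m6a.alphabet)
    assert back.stack == m6a.stack
    assert back.int22 == m6a.int22
    assert back.tstack == m6a.tstack


def test_table_sizes_grow_with_alphabet(rna, m6a):
    # 6 allowed pairs for rna, 8 for the m6A alphabet
    assert len(rna.stack) == 36 and len(m6a.stack) == 64
    assert len(rna.int22) == 6 * 6 * 4**4
    assert len(m6a.int22) == 8 * 8 * 5**4


def test_int22_loads_without_transposition(rna):
    """One entry checked against a hand-parsed line of the shipped file."""
    path = Path(__file__).parents[1] / "src/m6afold/data/rna/int22.tab"
    rows = [l.split() for l in path.read_text().splitlines()
            if l.strip() and not l.startswith("#")]
    # flattened order: (p1, p2, a, b, c) rows over pairs CG GC GU UG AU UA
    # and nucleotides A C G U; row index of (GC, UA, C, G, A) =
    pairs = ["CG", "GC", "GU", "UG", "AU", "UA"]
    nts = ["A", "C", "G", "U"]
    idx = ((((pairs.index("GC") * 6 + pairs.index("UA")) * 4
             + nts.index("C")) * 4 + nts.index("G")) * 4 + nts.index("A"))
    hand = float(rows[idx][nts.index("U")]) * 0.01  # scale directive
    assert rna.int22[("GC", "UA", "C", "G", "A", "U")] == pytest.approx(hand)


def test_missing_table_file_raises(rna, tmp_path):
    write_parameter_set(rna, tmp_path)
    (tmp_path / "int21.tab").unlink()
    with pytest.raises(ParameterError, match="int21"):
        read_parameter_set(tmp_path, rna.alphabet)


def test_dimension_mismatch_raises(rna, m6a, tmp_path):
    write_parameter_set(rna, tmp_path)
    with pytest.raises(ParameterError, match="dimension|cells"):
        read_parameter_set(tmp_path, m6a.alphabet)


def test_non_numeric_cell_raises(rna, tmp_path):
    write_parameter_set(rna, tmp_path)
    p = tmp_path / "stack.tab"
    p.write_text(p.read_text().replace("-2.36", "oops", 1))
    with pytest.raises(ParameterError, match="non-numeric"):
        read_parameter_set(tmp_path, rna.alphabet)


# ----------------------------------------------------------------------
# m6A construction rules

def test_contexts_enumeration():
    ctxs = m6a_stack_contexts()
    assert len(ctxs) == 15
    assert all("6" in a + b for a, b in ctxs)
    assert canonical_stack("AU", "6U") == ("6U", "AU")


def test_stacks_from_fitted_values(rna, m6a):
    assert m6a.stack[("6U", "AU")] == pytest.approx(-1.10)
    assert m6a.stack[("AU", "6U")] == m6a.stack[("6U", "AU")]


def test_dangle_rule_minus_0p4(rna, m6a):
    # contexts without a direct measurement: analog minus 0.4
    assert m6a.dangle3[("UA", "6")] == pytest.approx(
        rna.dangle3[("UA", "A")] - 0.4)
    # dangles on a 6-U closing pair mirror the A-U closure
    assert m6a.dangle5[("6U", "G")] == pytest.approx(rna.dangle5[("AU", "G")])
    assert m6a.dangle3[("6U", "6")] == pytest.approx(
        rna.dangle3[("AU", "A")] - 0.4)


def test_mismatch_rule_minus_0p3(rna, m6a):
    # single m6A in the mismatch: -0.3 (unmeasured context)
    assert m6a.tstack[("CG", "6", "C")] == pytest.approx(
        rna.tstack[("CG", "A", "C")] - 0.3)
    # m6A-m6A also only -0.3 (unmeasured context, e.g. on C-G closure)
    assert m6a.tstack[("GC", "6", "6")] == pytest.approx(
        rna.tstack[("GC", "A", "A")] - 0.3)
    # mismatch on a 6-U closing pair: additional -0.3 (additive: -0.6)
    assert m6a.tstack[("6U", "6", "G")] == pytest.approx(
        rna.tstack[("AU", "A", "G")] - 0.6)
    assert m6a.tstack[("U6", "C", "C")] == pytest.approx(
        rna.tstack[("UA", "C", "C")] - 0.3)


def test_loop_initiations_unchanged(rna, m6a):
    assert m6a.hairpin_init == rna.hairpin_init
    assert m6a.bulge_init == rna.bulge_init
    assert m6a.internal_init == rna.internal_init
    assert m6a.special_hairpins == rna.special_hairpins
    assert (m6a.ml_closing, m6a.ml_unpaired, m6a.ml_branch) == \
        (rna.ml_closing, rna.ml_unpaired, rna.ml_branch)


def test_small_loop_tables_closure_removed(rna, m6a):
    # unpaired m6A: analogous-A entry
    assert m6a.int11[("CG", "GC", "6", "G")] == \
        rna.int11[("CG", "GC", "A", "G")]
    # 6-U closure: analog A-U closure minus 0.7, per closing pair
    assert m6a.int22[("6U", "CG", "A", "C", "G", "U")] == pytest.approx(
        rna.int22[("AU", "CG", "A", "C", "G", "U")] - 0.7)
    assert m6a.int11[("6U", "U6", "C", "C")] == pytest.approx(
        rna.int11[("AU", "UA", "C", "C")] - 1.4)
    # interior terminal-stack tables likewise
    assert m6a.tstacki[("6U", "A", "G")] == pytest.approx(
        rna.tstacki[("AU", "A", "G")] - 0.7)
    assert m6a.tstacki1n[("U6", "C", "C")] == pytest.approx(
        rna.tstacki1n[("UA", "C", "C")] - 0.7)


def test_hairpin_mismatches_analog_only(rna, m6a):
    assert m6a.tstackh[("CG", "6", "G")] == rna.tstackh[("CG", "A", "G")]
    assert m6a.tstackh[("6U", "A", "A")] == rna.tstackh[("AU", "A", "A")]


def test_terminal_pair_penalties(rna, m6a, rna_legacy):
    assert rna.terminal_pair_penalty("AU") == pytest.approx(0.45)
    assert rna.terminal_pair_penalty("GU") == 0.0
    assert rna_legacy.terminal_pair_penalty("GU") == pytest.approx(0.45)
    assert m6a.terminal_pair_penalty("6U") == 0.0
    assert m6a.terminal_pair_penalty("U6") == 0.0
    assert m6a.terminal_pair_penalty("GC") == 0.0


def test_restriction_to_rna_is_identity(rna, m6a):
    sub = m6a.restricted_to_rna()
    for name in ("stack", "dangle5", "dangle3", "tstack", "tstackh",
                 "tstacki", "int11", "int21", "int22", "end_penalty"):
        assert getattr(sub, name) == getattr(rna, name), name


def test_measured_motif_changes_exactly_one_entry(rna):
    fitted = {k: 0.0 for k in m6a_stack_contexts()}
    base = build_m6a_tables(rna, fitted, [])
    probe = MeasuredMotif("dangle3", ("GC", "6"), -2.5, 0.1)
    mod = build_m6a_tables(rna, fitted, [probe])
    diffs = {k for k in base.dangle3 if base.dangle3[k] != mod.dangle3[k]}
    assert diffs == {("GC", "6")}
    assert mod.dangle3[("GC", "6")] == -2.5
    assert base.dangle5 == mod.dangle5 and base.tstack == mod.tstack


def test_missing_fitted_stack_context_raises(rna):
    fitted = {k: 0.0 for k in m6a_stack_contexts()[:-1]}
    with pytest.raises(ParameterError, match="missing fitted stack"):
        build_m6a_tables(rna, fitted, [])


def test_unknown_measured_context_raises(rna):
    fitted = {k: 0.0 for k in m6a_stack_contexts()}
    with pytest.raises(ParameterError):
        build_m6a_tables(rna, fitted,
                         [MeasuredMotif("dangle3", ("GG", "6"), -1.0)])


# ----------------------------------------------------------------------
# table symmetries

@pytest.mark.parametrize("which", ["rna", "m6a"])
def test_stack_strand_reversal_symmetry(rna, m6a, which):
    ps = {"rna": rna, "m6a": m6a}[which]
    for (p1, p2), v in ps.stack.items():
        assert ps.stack[(p2, p1)] == v


@pytest.mark.parametrize("which", ["rna", "m6a"])
def test_interior_loop_table_symmetry(rna, m6a, which):
    ps = {"rna": rna, "m6a": m6a}[which]
    for (p1, p2, x, y), v in ps.int11.items():
        assert ps.int11[(p2, p1, y, x)] == pytest.approx(v)
    for (p1, p2, a, b, c, d), v in ps.int22.items():
        assert ps.int22[(p2, p1, c, d, a, b)] == pytest.approx(v)


def test_all_tables_fully_populated(m6a):
    pairs = m6a.pair_names
    nts = m6a.alphabet.nucleotides
    for p in pairs:
        for x in nts:
            assert (p, x) in m6a.dangle5 and (p, x) in m6a.dangle3
            for y in nts:
                for t in (m6a.tstack, m6a.tstackh, m6a.tstacki,
                          m6a.tstacki1n, m6a.tstacki23, m6a.tstackm):
                    assert (p, x, y) in t
    for n in range(3, 31):
        assert n in m6a.hairpin_init
    for n in range(1, 31):
        assert n in m6a.bulge_init
    for v in m6a.stack.values():
        assert math.isfinite(v)
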