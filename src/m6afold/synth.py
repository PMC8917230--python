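"""Synthetic study generator.

Everything the test-suite and the reproduction script consume is generated
here, from the package's own thermodynamic model plus explicitly labelled
synthetic study conditions:

* a database of fully helical duplexes with m6A-U pairs covering all 15
  stack contexts (including a pair of helices that share every stack but
  differ in their terminal pairs);
* loop-motif experiments (dangling ends, terminal mismatches, a stem-loop,
  a tandem G-m6A interior loop) with analogous-A controls;
* two-state optical melts of those duplexes at nine strand concentrations,
  from which stabilities are re-fitted exactly the way a melting study
  analyses real curves;
* random fold-test sequences carrying the GGACU methylation consensus and
  synthetic S1/V1 nuclease count tracks.

The synthetic "truth" is the shipped m6A parameter model, plus effects the
model deliberately omits and a study would still observe: a small real
terminal m6A-U stability cost (+0.13 kcal/mol per terminal pair, which the
diagnostic regression column recovers but the production model drops), the
hairpin-loop methylation penalty (+0.23) and the tandem G-m6A interior
loop penalty (+0.33) that the loop tables treat as analogous to A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import DuplexSpec, duplex_energy, structure_energy
from .fold import mfe_fold, partition
from .melting import (VantHoffFit, fit_single_curve, fit_tm_plot,
                      melting_temperature, simulate_melt_curve,
                      two_state_check)
from .params import NNParameterSet, load_m6a_params, load_rna_params
from .structure import SecondaryStructure

#: real (synthetic-truth) stability cost of a terminal m6A-U pair that the
#: production parameter model omits, kcal/mol per helix end
TERMINAL_6U_TRUE = 0.13
#: methylation penalty of the stem-loop hairpin motif, kcal/mol
HAIRPIN_METHYL_TRUE = 0.23
#: methylation penalty of the tandem G-m6A 2x2 interior loop, kcal/mol
INTERNAL_METHYL_TRUE = 0.33
#: absorbance noise (a.u.) of a synthetic melting curve
MELT_NOISE_SD = 0.003

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G", "6": "U"}


def _frame_duplex(top_mid: str, bottom_mid: str) -> DuplexSpec:
    """An 8-mer helix G G C <top_mid> G C C paired against
    C C G <bottom_mid> C G G (bottom written 3'->5')."""
    top = "GGC" + top_mid + "GCC"
    bottom3to5 = "CCG" + bottom_mid + "CGG"
    return DuplexSpec(top, bottom3to5[::-1])


def stack_study_duplexes() -> list[DuplexSpec]:
    """The 32 fully helical duplexes of the synthetic stack database."""
    mids = [
        # one per central m6A dinucleotide (top/bottom, bottom written 3'->5')
        ("6A", "UU"), ("66", "UU"), ("6U", "U6"), ("U6", "6U"),
        ("6C", "UG"), ("6G", "UC"), ("6G", "UU"), ("6U", "UG"),
        ("A6", "UU"), ("C6", "GU"), ("G6", "CU"), ("G6", "UU"),
        ("U6", "AU"), ("U6", "GU"), ("6U", "UA"),
    ]
    duplexes = [_frame_duplex(t, b) for t, b in mids]
    # richer multi-methylation and wobble-flanked helices
    extra = [
        ("GGC6UAGCC", "CCGU6UCGG"), ("GC6AU6AGC", "CGUU6UUCG"),
        ("GG6CU6GCC", "CCUG6UCGG"), ("GCU66AGGC", "CGAUUUCCG"),
        ("GGU6ACGCC", "CCGUUGCGG"), ("GC6GA6CGC", "CGUCUUGCG"),
        ("GGCA6UGCC", "CCGUUACGG"), ("GG6UGCGCC", "CCUGCGCGG"),
        # single terminal m6A-U pairs (break the stack-orientation parity)
        ("6GCGC", "UCGCG"), ("GCGC6", "CGCGU"),
        ("GCC6AGGC", "CGGUUCCG"), ("GG6A6CCC", "CCUUUGGG"),
        ("GGG6ACCC", "CCCUUGGG"), ("GC6ACGGC", "CGUUGCCG"),
        ("CGG6ACCG", "GCCUUGGC"),
    ]
    for top, bottom3 in extra:
        duplexes.append(DuplexSpec(top, bottom3[::-1]))
    # the helix-end test pair: identical stack multisets, one helix with
    # two terminal m6A-U pairs, the other with C-G ends
    duplexes.append(DuplexSpec("6CGGC6", "UGCCGU"[::-1]))
    duplexes.append(DuplexSpec("CGGC6C", "GCCGUG"[::-1]))
    assert len(duplexes) == 32
    return duplexes


HELIX_END_PAIR = ("6CGGC6", "CGGC6C")  # strand1 names of the end-test pair


def true_duplex_dg37(m6a: NNParameterSet, duplex: DuplexSpec) -> float:
    """Synthetic-truth stability: model prediction plus the real terminal
    m6A-U cost the model omits."""
    s1, s2, _ = duplex.resolved(m6a)
    n_term_6u = 0
    for pair in (s1[0] + s2[-1], s2[0] + s1[-1]):
        if "6" in pair and "U" in pair:
            n_term_6u += 1
    return duplex_energy(m6a, duplex) + TERMINAL_6U_TRUE * n_term_6u


@dataclass(frozen=True)
class MeltExperiment:
    """A simulated nine-concentration optical melting study of one duplex."""

    fit: VantHoffFit           # from the T_M^-1 vs ln(C_T/a) analysis
    dh_curve_mean: float       # mean dH of the individual curve fits
    two_state: bool


def melt_experiment(dg37_true: float, seed: int, a: int = 4,
                    noise_sd: float = MELT_NOISE_SD,
                    n_conc: int = 9) -> MeltExperiment:
    """Simulate melting curves for a duplex of known stability and re-fit.

    Strand concentrations span 0.1 mM to 1 uM.  The generating enthalpy is
    drawn from the realistic range dH = (6..8.5) x dG37.
    """
    rng = np.random.default_rng(seed)
    ratio = rng.uniform(6.0, 8.5)
    dh = dg37_true * ratio
    ds = (dh - dg37_true) / 310.15
    fits = []
    points = []
    for ct in np.geomspace(1e-4, 1e-6, n_conc):
        curve = simulate_melt_curve(
            dh, ds, float(ct), a, noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)))
        f = fit_single_curve(curve)
        fits.append(f)
        points.append((float(ct), melting_temperature(f.dH, f.dS, float(ct), a)))
    tm_fit = fit_tm_plot(points, a)
    dh_curves = float(np.mean([f.dH for f in fits]))
    return MeltExperiment(fit=tm_fit, dh_curve_mean=dh_curves,
                          two_state=two_state_check(dh_curves, tm_fit.dH))


def stack_study(seed: int, via_melting: bool = True) -> pd.DataFrame:
    """The synthetic 32-duplex database with experimental stabilities.

    ``via_melting=True`` runs the full pipeline (simulate curves at nine
    concentrations, fit each, fit the T_M plot); otherwise Gaussian noise
    at the 4% convention is applied directly to the true stabilities.
    """
    rna = load_rna_params()
    m6a = load_m6a_params()
    rng = np.random.default_rng(seed)
    rows = []
    for k, duplex in enumerate(stack_study_duplexes()):
        truth = true_duplex_dg37(m6a, duplex)
        # per-sample systematic error of an optical melting study (strand
        # concentration / extinction coefficients): 2% of |dG|, half the
        # conservative 4% convention
        sample = truth + rng.normal(0.0, 0.02 * abs(truth))
        if via_melting:
            exp = melt_experiment(sample, seed=int(rng.integers(0, 2**31 - 1)))
            dg = exp.fit.dG37
            two_state = exp.two_state
        else:
            dg = sample + rng.normal(0.0, 0.02 * abs(truth))
            two_state = True
        rows.append({
            "strand1": duplex.strand1, "strand2": duplex.strand2,
            "dg37_true": truth, "dg37": dg, "two_state": two_state,
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# loop-motif study

_DANGLE_CORES = {
    # closing pair (read toward the dangle) -> self-complementary core
    "CG": "CGCGCG",
    "GC": "GGCGCC",
    "AU": "AGCGCU",
}


def _dangle_duplex(core: str, nt: str) -> DuplexSpec:
    """Self-complementary duplex with a 3' dangle *nt* on both ends."""
    n = len(core)
    strand = core + nt
    pairs = tuple((i, n + 1 - i) for i in range(1, n + 1))
    return DuplexSpec(strand, strand, self_complementary=True, pairs=pairs)


def _dangle5_duplex(core: str, nt: str) -> DuplexSpec:
    """Self-complementary duplex with a 5' dangle *nt* on both ends."""
    n = len(core)
    strand = nt + core
    pairs = tuple((i, n + 3 - i) for i in range(2, n + 2))
    return DuplexSpec(strand, strand, self_complementary=True, pairs=pairs)


def _mismatch_duplex(pair: str, x: str, y: str) -> DuplexSpec:
    """Self-complementary duplex with terminal mismatch (x, y) on closing
    pair *pair* at both ends."""
    strand = x + pair[0] + "CGCG" + pair[1] + y
    n = len(strand)
    pairs = tuple((i, n + 1 - i) for i in range(2, n))
    return DuplexSpec(strand, strand, self_complementary=True, pairs=pairs)


HAIRPIN_SEQ = "GGCGUAAUAGCC"          # m6A analog position 6
HAIRPIN_SEQ_M = "GGCGU6AUAGCC"
HAIRPIN_STEM = ((1, 12), (2, 11), (3, 10))
INTERNAL_SEQ = "GCGGACGC"             # tandem G-A 2x2 loop homodimer
INTERNAL_SEQ_M = "GCGG6CGC"
INTERNAL_PAIRS = ((1, 8), (2, 7), (3, 6), (6, 3), (7, 2), (8, 1))

#: measured dangling-end and terminal-mismatch motif contexts
#: (kind, closing pair, nucleotides) -- methylated and analogous-A forms
#: are generated for each
DANGLE_MOTIFS = (("CG", "6"), ("GC", "6"), ("AU", "6"))
DANGLE_5P_MOTIFS = (("CG", "6"),)
MISMATCH_MOTIFS = (("UG", "G", "6"), ("AU", "G", "6"), ("AU", "6", "6"),
                   ("GC", "6", "C"), ("CG", "6", "G"), ("GC", "6", "G"),
                   ("UA", "6", "C"))


def _hairpin_truth(params_rna, params_m6a):
    st = SecondaryStructure(len(HAIRPIN_SEQ), HAIRPIN_STEM)
    t_a = structure_energy(params_rna, HAIRPIN_SEQ, st)
    t_m = structure_energy(params_m6a, HAIRPIN_SEQ_M, st) + HAIRPIN_METHYL_TRUE
    stacks = sum(params_rna.stack[k] for k in (("GC", "CG"), ("GC", "GC")))
    return t_a, t_m, stacks


def motif_study(seed: int, via_melting: bool = False) -> pd.DataFrame:
    """Loop-motif experiments: stabilities of motif-bearing duplexes and
    their references, methylated and analogous-A forms."""
    rna = load_rna_params()
    m6a = load_m6a_params()
    rng = np.random.default_rng(seed)
    rows = []

    def observe(name, kind, truth, a=1):
        if via_melting:
            exp = melt_experiment(truth, seed=int(rng.integers(0, 2**31 - 1)),
                                  a=a)
            dg = exp.fit.dG37
        else:
            # the repeatability of a nine-concentration analysis, tighter
            # than the 4% systematic convention
            dg = truth + rng.normal(0.0, 0.08)
        rows.append({"name": name, "kind": kind,
                     "dg37_true": truth, "dg37": dg})

    for pair, nt in DANGLE_MOTIFS:
        core = _DANGLE_CORES[pair]
        observe(f"core_{pair}", "reference", duplex_energy(m6a, DuplexSpec(
            core, core, self_complementary=True)))
        for label, params, x in (("m", m6a, nt), ("a", rna, "A")):
            observe(f"dangle3_{pair}_{x}", "dangle3",
                    duplex_energy(params, _dangle_duplex(core, x)))
    for pair, nt in DANGLE_5P_MOTIFS:
        core = _DANGLE_CORES[pair]
        observe("core5_CG", "reference", duplex_energy(m6a, DuplexSpec(
            core, core, self_complementary=True)))
        for params, x in ((m6a, nt), (rna, "A")):
            observe(f"dangle5_{pair}_{x}", "dangle5",
                    duplex_energy(params, _dangle5_duplex(core, x)))

    seen_cores: set[str] = set()
    for pair, x, y in MISMATCH_MOTIFS:
        core = pair[0] + "CGCG" + pair[1]
        if pair not in seen_cores:
            seen_cores.add(pair)
            observe(f"mmcore_{pair}", "reference", duplex_energy(
                m6a, DuplexSpec(core, core, self_complementary=True)))
        observe(f"mm_{pair}_{x}{y}", "terminal_mismatch",
                duplex_energy(m6a, _mismatch_duplex(pair, x, y)))
        ax, ay = x.replace("6", "A"), y.replace("6", "A")
        observe(f"mm_{pair}_{ax}{ay}a", "terminal_mismatch",
                duplex_energy(rna, _mismatch_duplex(pair, ax, ay)))

    t_a, t_m, stacks = _hairpin_truth(rna, m6a)
    observe("hairpin_A", "hairpin", t_a)
    observe("hairpin_m6A", "hairpin", t_m)
    rows.append({"name": "hairpin_stacks", "kind": "reference",
                 "dg37_true": stacks, "dg37": stacks})

    for name, seq, params, excess in (
            ("internal_A", INTERNAL_SEQ, rna, 0.0),
            ("internal_m6A", INTERNAL_SEQ_M, m6a, INTERNAL_METHYL_TRUE)):
        d = DuplexSpec(seq, seq, self_complementary=True,
                       pairs=INTERNAL_PAIRS)
        observe(name, "internal", duplex_energy(params, d) + excess, a=1)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# folding fixtures

def consensus_site_sequences(seed: int, n: int = 10, flank: int = 5,
                             mismatches: int = 4):
    """Random stem-loop-forming sequences with the GGACU consensus inside
    the stem, so the consensus A pairs with a U and methylation perturbs
    two helix stacks.  A few seeded mismatches keep the stem marginal, so
    the site is buried with intermediate probability and the ensemble
    responds to methylation.  Returns (sequence, 1-based site) pairs."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        left = "".join(rng.choice(list("ACGU"), size=flank))
        loop = "".join(rng.choice(list("ACU"), size=4))
        stem5 = left + "GGACU"
        right = list(_COMP[c] for c in reversed(stem5))
        for pos in rng.choice(len(right), size=mismatches, replace=False):
            right[pos] = rng.choice([c for c in "ACGU" if c != right[pos]])
        seq = stem5 + loop + "".join(right)
        out.append((seq, flank + 3))  # 1-based position of the consensus A
    return out


def synthetic_nuclease_tracks(seq: str, params=None, seed: int = 0,
                              depth: float = 40.0):
    """Synthetic S1/V1 per-nucleotide counts: V1 (helix-specific) rates
    follow the pairing probability of the Boltzmann ensemble, S1
    (loop-specific) rates its complement."""
    if params is None:
        params = load_rna_params()
    pr = partition(params, seq)
    p_paired = pr.pairprob.sum(axis=0)[1:]
    rng = np.random.default_rng(seed)
    v1 = rng.poisson(2.0 + depth * p_paired)
    s1 = rng.poisson(2.0 + depth * (1.0 - p_paired))
    return v1.astype(int), s1.astype(int)


# ----------------------------------------------------------------------
# file-based fixture suite

def generate_fixture_suite(seed: int, outdir) -> dict:
    """Write the delimited fixture files shared by tests and the CLI:
    melting curves, the duplex tables, fold-test FASTA, count tracks.
    Deterministic in *seed*; returns the paths."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    curve = simulate_melt_curve(-62.0, -0.17, 1e-4, 4,
                                noise_sd=MELT_NOISE_SD, seed=seed)
    p = out / "melt_curve.tsv"
    pd.DataFrame({"temperature_C": curve.temperatures,
                  "A260": curve.absorbance}).to_csv(p, sep="\t", index=False)
    paths["melt_curve"] = p

    df = stack_study(seed, via_melting=False)
    p = out / "stack_duplexes.tsv"
    df.to_csv(p, sep="\t", index=False)
    paths["stack_duplexes"] = p

    df = motif_study(seed)
    p = out / "motif_duplexes.tsv"
    df.to_csv(p, sep="\t", index=False)
    paths["motif_duplexes"] = p

    seqs = consensus_site_sequences(seed)
    p = out / "consensus_sites.fasta"
    with open(p, "w") as fh:
        for k, (seq, site) in enumerate(seqs):
            fh.write(f">site_{k} consensus_A={site}\n{seq}\n")
    paths["consensus_sites"] = p

    seq, site = seqs[0]
    v1, s1 = synthetic_nuclease_tracks(seq, seed=seed)
    p = out / "nuclease_counts.tsv"
    pd.DataFrame({"position": np.arange(1, len(seq) + 1),
                  "v1": v1, "s1": s1}).to_csv(p, sep="\t", index=False)
    paths["nuclease_counts"] = p
    return paths
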