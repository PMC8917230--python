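"""End-to-end analyses of the synthetic m6A thermodynamics study.

Each function runs one slice of the full pipeline -- simulate optical
melts, re-fit stabilities, regress stack parameters, extract loop-motif
increments, fold, and score accessibility -- and returns the summary
quantities a melting/folding study reports.  The reproduction script and
the acceptance tests call these functions; nothing here reads files.
"""

from __future__ import annotations

import math
import random

import numpy as np

from .constants import RT37
from .energy import DuplexSpec, duplex_energy, structure_energy
from .fold import (enumerate_structures, mfe_fold, opening_cost, partition,
                   window_profile)
from .melting import (fit_single_curve, fit_tm_plot, melting_temperature,
                      motif_increment_hairpin, motif_increment_internal,
                      motif_increment_terminal, simulate_melt_curve)
from .nnfit import StackRegression, methylation_ddg_summary
from .params import load_m6a_params, load_rna_params
from .pars import NucleaseCounts, pars_scores, site_profile
from .structure import SecondaryStructure
from .synth import (DANGLE_MOTIFS, DANGLE_5P_MOTIFS, HAIRPIN_STEM,
                    HELIX_END_PAIR, INTERNAL_SEQ, MISMATCH_MOTIFS,
                    consensus_site_sequences, melt_experiment, motif_study,
                    stack_study, synthetic_nuclease_tracks)

#: reference experimental stabilities (kcal/mol) of the GGACU-consensus
#: duplex GGACUAGUCC and its doubly methylated form, synthetic
#: reconstructions anchored to published optical melting summary results
CONSENSUS_EXPT_UNMETH = -16.19
CONSENSUS_EXPT_METH = -15.45

MALAT1 = "AACUUAAUGUUUUUGCAUUGGACUUUGAGUUA"
MALAT1_OPEN_PAIRS = {(10, 22), (11, 21), (12, 20)}


# ----------------------------------------------------------------------
# helix stack regression

def run_stack_analysis(seed: int, via_melting: bool = True) -> dict:
    """The full stack study: melts -> stabilities -> OLS fit -> summary."""
    rna = load_rna_params()
    m6a = load_m6a_params()
    df = stack_study(seed, via_melting=via_melting)
    data = [(DuplexSpec(r.strand1, r.strand2), r.dg37)
            for r in df.itertuples()]
    res = StackRegression(data, rna, m6a).fit()
    diag = StackRegression(data, rna, m6a, include_terminal=True).fit()
    dd = methylation_ddg_summary(res, rna)
    e = df.set_index("strand1")["dg37"]
    return {
        "n_duplexes": len(df),
        "r_squared": res.r_squared,
        "mean_ddg_per_methylation": dd.attrs["mean_ddg_per_methyl"],
        "stack_6u_ua": res.coefficients["6U/AU"],
        "stack_6u_ua_se": res.standard_errors["6U/AU"],
        "terminal_term": diag.terminal_term[0],
        "terminal_term_se": diag.terminal_term[1],
        "helix_end_difference": float(e[HELIX_END_PAIR[0]]
                                      - e[HELIX_END_PAIR[1]]),
        "two_state_fraction": float(df.two_state.mean()),
        "result": res,
    }


# ----------------------------------------------------------------------
# loop motifs

def run_motif_analysis(seed: int) -> dict:
    """Dangling-end / terminal-mismatch / hairpin / interior-loop
    methylation effects from the synthetic motif experiments."""
    rna = load_rna_params()
    df = motif_study(seed).set_index("name")["dg37"]

    dangle_ddg = []
    for pair, nt in DANGLE_MOTIFS:
        core = df[f"core_{pair}"]
        m = motif_increment_terminal(df[f"dangle3_{pair}_{nt}"], core)
        a = motif_increment_terminal(df[f"dangle3_{pair}_A"], core)
        dangle_ddg.append(m - a)
    for pair, nt in DANGLE_5P_MOTIFS:
        core = df["core5_CG"]
        m = motif_increment_terminal(df[f"dangle5_{pair}_{nt}"], core)
        a = motif_increment_terminal(df[f"dangle5_{pair}_A"], core)
        dangle_ddg.append(m - a)

    mismatch_ddg = []
    for pair, x, y in MISMATCH_MOTIFS:
        core = df[f"mmcore_{pair}"]
        m = motif_increment_terminal(df[f"mm_{pair}_{x}{y}"], core)
        ax, ay = x.replace("6", "A"), y.replace("6", "A")
        a = motif_increment_terminal(df[f"mm_{pair}_{ax}{ay}a"], core)
        mismatch_ddg.append(m - a)

    stacks = df["hairpin_stacks"]
    hairpin_ddg = (motif_increment_hairpin(df["hairpin_m6A"], stacks)
                   - motif_increment_hairpin(df["hairpin_A"], stacks))

    # interior loop: subtract the four stem stacks, initiation and symmetry
    stem = 2 * (rna.stack[("GC", "GC")] + rna.stack[("CG", "CG")])
    internal_ddg = (
        motif_increment_internal(df["internal_m6A"], stem,
                                 rna.duplex_init, rna.symmetry_corr)
        - motif_increment_internal(df["internal_A"], stem,
                                   rna.duplex_init, rna.symmetry_corr))
    return {
        "dangle_mean_ddg": float(np.mean(dangle_ddg)),
        "mismatch_mean_ddg": float(np.mean(mismatch_ddg)),
        "hairpin_ddg": float(hairpin_ddg),
        "internal_loop_ddg": float(internal_ddg),
        "n_dangles": len(dangle_ddg),
        "n_mismatches": len(mismatch_ddg),
    }


# ----------------------------------------------------------------------
# parameter tests on duplexes

def consensus_duplex_deviation() -> dict:
    """Nearest-neighbor estimate minus reference experiment for the
    consensus-site duplex, unmethylated and methylated."""
    rna = load_rna_params()
    m6a = load_m6a_params()
    est_a = duplex_energy(rna, "GGACUAGUCC")
    est_m = duplex_energy(m6a, "GG6CUAGUCC")
    return {
        "nn_estimate_unmethylated": est_a,
        "nn_minus_experiment_unmethylated": est_a - CONSENSUS_EXPT_UNMETH,
        "nn_estimate_methylated": est_m,
        "nn_minus_experiment_methylated": est_m - CONSENSUS_EXPT_METH,
    }


def malat1_analysis() -> dict:
    """Stem-loop accessibility shift of the HNRNPC site on methylation."""
    rna = load_rna_params()
    m6a = load_m6a_params()
    met = MALAT1[:21] + "6" + MALAT1[22:]
    closed = mfe_fold(rna, MALAT1).structure
    closed_m = mfe_fold(m6a, met).structure
    open_ = SecondaryStructure(32, closed.pairs - MALAT1_OPEN_PAIRS)
    cost_a = opening_cost(rna, MALAT1, closed, open_)
    cost_m = opening_cost(m6a, met, closed, open_)
    return {
        "same_mfe_pairs": closed.pairs == closed_m.pairs,
        "opening_cost_unmethylated": cost_a,
        "opening_cost_methylated": cost_m,
        "opening_ddg": cost_a - cost_m,
    }


# ----------------------------------------------------------------------
# folding oracle agreement (ensemble convention)

def folding_oracle_check(seed: int, n_sequences: int = 50,
                         max_len: int = 16) -> dict:
    """MFE, partition function, pair and buried probabilities of the
    dynamic programs against exhaustive enumeration."""
    rna = load_rna_params()
    m6a = load_m6a_params()
    rng = random.Random(seed)
    mfe_hits = 0
    worst_q = worst_pp = worst_b = 0.0
    for t in range(n_sequences):
        params = m6a if t % 3 == 0 else rna
        alpha = "ACGU6" if t % 3 == 0 else "ACGU"
        n = rng.randint(10, max_len)
        seq = "".join(rng.choice(alpha) for _ in range(n))
        structs = list(enumerate_structures(params, seq))
        emin = min(e for _, e in structs)
        z = sum(math.exp(-e / RT37) for _, e in structs)
        pp = np.zeros((n + 1, n + 1))
        bur = np.zeros(n + 1)
        for st, e in structs:
            w = math.exp(-e / RT37) / z
            for (i, j) in st.pairs:
                pp[i, j] += w
                if i > 1 and j < n and (i - 1, j + 1) in st.pairs \
                        and (i + 1, j - 1) in st.pairs:
                    bur[i] += w
                    bur[j] += w
        res = mfe_fold(params, seq)
        pr = partition(params, seq)
        mfe_hits += abs(res.dg37 - emin) < 1e-9
        worst_q = max(worst_q, abs(pr.Q - z) / z)
        worst_pp = max(worst_pp, float(np.abs(
            np.triu(pp) - np.triu(pr.pairprob)).max()))
        worst_b = max(worst_b, float(np.abs(bur - pr.buried).max()))
    return {
        "n_sequences": n_sequences,
        "mfe_agreement_fraction": mfe_hits / n_sequences,
        "max_partition_rel_error": worst_q,
        "max_pairprob_error": worst_pp,
        "max_buried_error": worst_b,
    }


# ----------------------------------------------------------------------
# melting recovery

def melting_recovery_check(seed: int) -> dict:
    """Noiseless recovery of generating parameters by both fit routes,
    and the 15% two-state criterion on noisy synthetic melts."""
    dh, ds = -65.0, -0.18
    curve_fit_ = fit_single_curve(simulate_melt_curve(dh, ds, 1e-4, 4))
    pts = [(ct, melting_temperature(dh, ds, float(ct), 4))
           for ct in np.geomspace(1e-4, 1e-6, 9)]
    tm_fit = fit_tm_plot(pts, 4)
    exps = [melt_experiment(dg, seed=seed + k, a=4)
            for k, dg in enumerate((-9.0, -11.5, -14.0))]
    return {
        "curvefit_dh_rel_error": abs(curve_fit_.dH - dh) / abs(dh),
        "curvefit_ds_rel_error": abs(curve_fit_.dS - ds) / abs(ds),
        "tmplot_dh_rel_error": abs(tm_fit.dH - dh) / abs(dh),
        "tmplot_dg37_rel_error": abs(tm_fit.dG37 - (dh - 310.15 * ds))
        / abs(dh - 310.15 * ds),
        "two_state_pass_fraction": float(np.mean(
            [e.two_state for e in exps])),
    }


# ----------------------------------------------------------------------
# accessibility demonstration

def buried_site_demo(seed: int, n_sites: int = 8, window: int = 44) -> dict:
    """Scaled demonstration of the transcriptome-wide comparison: mean
    probability of the consensus A being buried in a helix, with and
    without methylation, over synthetic stem-loop fixtures."""
    rna = load_rna_params()
    m6a = load_m6a_params()
    half = max(1, n_sites // 2)
    sites = (consensus_site_sequences(seed, n=half, mismatches=3)
             + consensus_site_sequences(seed + 1, n=n_sites - half,
                                        mismatches=4))
    p_a, p_m = [], []
    for seq, site in sites:
        met = seq[:site - 1] + "6" + seq[site:]
        wa = window_profile(rna, seq, site, window=window)
        wm = window_profile(m6a, met, site, window=window)
        p_a.append(float(wa.buried[wa.site_offset - 1]))
        p_m.append(float(wm.buried[wm.site_offset - 1]))
    return {
        "n_sites": n_sites,
        "site_buried_percent_unmethylated": 100.0 * float(np.mean(p_a)),
        "site_buried_percent_methylated": 100.0 * float(np.mean(p_m)),
    }


def pars_demo(seed: int, n_sites: int = 6) -> dict:
    """Synthetic PARS tracks around consensus sites: scores at the site
    versus the flanks, plus the exact score identities."""
    rna = load_rna_params()
    site_scores, flank_scores = [], []
    for k, (seq, site) in enumerate(consensus_site_sequences(seed,
                                                             n=n_sites)):
        v1, s1 = synthetic_nuclease_tracks(seq, rna, seed=seed + k)
        track = pars_scores(NucleaseCounts(v1, s1))
        prof = site_profile(track, site, flank=10)
        site_scores.append(prof[0])
        flank_scores.extend(v for o, v in prof.items() if abs(o) >= 6)
    zero = pars_scores(NucleaseCounts([0], [0], 10, 10)).scores[0]
    a = pars_scores(NucleaseCounts([11], [3], 50, 50)).scores[0]
    b = pars_scores(NucleaseCounts([11], [3], 100, 100)).scores[0]
    return {
        "mean_site_pars": float(np.mean(site_scores)),
        "mean_flank_pars": float(np.mean(flank_scores)),
        "zero_count_score": float(zero),
        "ratio_invariance_error": float(abs(a - b)),
        "example_score_11_3": float(a),
    }
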