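# Methods

## The model

`m6afold` implements the nearest-neighbor free-energy model of RNA
secondary structure at 37 °C over a user-defined nucleotide alphabet, with
the five-letter alphabet {A, C, G, U, 6} (6 = N6-methyladenosine) as the
shipped extension. Folding free energy is a sum over loops: helix stacks,
hairpin loops, bulge and interior loops, multibranch loops with a linear
(a + b·unpaired + c·branches) model, and the exterior loop. All energies
are ΔG°37 in kcal/mol; R = 1.9872×10⁻³ kcal/(mol·K), T = 310.15 K. There
is no temperature dependence outside the melting module: enthalpy tables
for the modified alphabet do not exist, so the package deliberately works
at 37 °C only.

### Baseline tables

The rna tables are the 2004-generation Turner rules: Watson–Crick stacks
at the printed 0.01 kcal/mol precision of Xia et al., G-U stacks and all
loop tables as tabulated in the public Nearest Neighbor Database
distribution of those rules, duplex initiation +4.09, symmetry correction
+0.43, terminal A-U penalty +0.45 per helix end. Two conventions depart
from the strict 2004 rules and are deliberate package defaults:

* terminal G-U pairs carry **no** helix-end penalty (the revised wobble
  convention the m6A set assumes); `--legacy-gu-end` (or
  `load_rna_params(legacy_gu_end=True)`) restores the 2004 behaviour of
  penalizing any terminal pair containing U;
* hairpin first-mismatch bonuses are carried inside the hairpin mismatch
  table; the oligo-C hairpin terms and the GG-preceded G-U closure bonus
  are applied separately, as in the published 2004 description.

Tables live in `src/m6afold/data/rna/` in a whitespace-delimited text
dialect (one file per table, `#` comments carrying the index order, `NA`
for disallowed contexts, an optional `scale:` directive used by the large
interior-loop files). `read_parameter_set`/`write_parameter_set`
round-trip every value exactly; values are quantized to 10⁻⁶ kcal/mol on
read to keep derived tables round-trippable.

### The m6A extension

The m6A set is never stored expanded; `build_m6a_tables` derives it from
the rna set plus two small data files, following fixed precedence rules
(measured motif values first, then fitted m6A-U helix stacks, then
analogy rules: dangling m6A = analogous A − 0.4 kcal/mol; m6A-containing
terminal mismatches = analogous A − 0.3, with a further −0.3 when the
closing pair is m6A-U; interior-loop entries inherit analogous-A values
with the +0.7 A-U closure penalty removed for m6A-U closures; loop
initiations, special hairpins and multibranch constants unchanged;
terminal m6A-U pairs penalty-free). The −0.4/−0.3 increments are applied
uniformly wherever the dangle/mismatch tables are consulted, including
multibranch and exterior contexts; the hairpin-closure mismatch table
keeps pure analogous-A values.

**The shipped m6A-U stack table and measured-motif list are synthetic
reference reconstructions** (`fitted_stacks_synthetic.tab`,
`measured_motifs_synthetic.tab`): analogous-A values plus methylation
increments anchored to published optical-melting summary results for m6A
(the m6A-U/U-A stack equal to its A-U analog at −1.10 kcal/mol; the most
stable m6A stack at −1.79; the doubly methylated stack at +1.45 as the
least stable; a mean destabilization of +0.40 kcal/mol per methylation
across the 15 contexts; dangling-end increments averaging −0.43;
terminal-mismatch increments averaging −0.28 and spanning −0.74 to
+0.02; and the 0.6 kcal/mol stem-loop opening-cost shift of the HNRNPC
demonstration, which pins the sum of the two stack increments it
involves). Individual unanchored entries are package choices within those
constraints and are documented in the data files themselves.

## Energy evaluation conventions

Two decoration conventions exist for helix ends in multibranch and
exterior loops:

* **efn2 convention** (default for `structure_energy` and
  `duplex_energy`): every unpaired nucleotide adjacent to a helix end
  contributes the more favourable of its 5'/3' dangle options, counted
  once; coaxial stacking is found by exhaustive enumeration of
  non-overlapping flush (helix-stack energy) and single-mismatch
  (multibranch-stack + sequence-independent −2.1 kcal/mol) junctions per
  loop.
* **ensemble convention** (`ENSEMBLE_OPTIONS`; used by `mfe_fold`,
  `partition` and `enumerate_structures`): each helix end contributes a
  terminal-stack term computed from both neighbouring bases regardless of
  their pairing state, and coaxial stacking is off.

The ensemble convention exists because the per-nucleotide best-dangle rule
does not decompose: the shared nucleotide between two abutting helices
couples their identities, which is expressible in a minimization DP only
through case explosion and not at all in an O(n³) partition function
(summing over the two assignments double-counts structures). The
both-neighbour terminal-stack rule decomposes exactly, so the MFE search,
the partition function, the exhaustive enumerator and the evaluator agree
structure by structure to machine precision — which is what the oracle
tests assert, and what makes the base-pair and buried probabilities
exact expectations over the same ensemble the MFE belongs to. The
restricted evaluator reproduces an independent implementation of the same
published tables (RNAeval on the Turner-2004 parameter file, d2 dangles)
to the printed 0.01 kcal/mol on every loop type; the cross-check
structures avoid penalized helix ends because this package keeps the
printed +0.45 A-U end value while the external file rounds it to 0.50.

Interior loops use the standard decomposition: 1×1/2×1/2×2 lookup
tables; 1×n and 2×3 loops with their dedicated terminal-stack tables;
otherwise initiation + 0.6·|n₁−n₂| asymmetry (capped at 3.0) + generic
interior terminal stacks. Single bulges keep the cross stack and ignore
the bulged base's identity; larger bulges add both helix-end penalties.
Loop initiations beyond 30 extrapolate as ΔG(30) + 1.07856·ln(n/30).

## Folding dynamic programs

Minimum free energy and partition function are O(n³) nested-structure
recursions over the ensemble convention: lonely pairs allowed, hairpin
loops ≥ 3 nt, interior loops capped at 30 unpaired nucleotides. MFE
traceback is deterministic (first decomposition found scanning pairing
partners and split points in ascending order). The partition function is
McCaskill inside/outside; pair probabilities come from
p(i,j) = V(i,j)·V'(i,j)/Q, and the buried-in-helix probability is

    P_i = (1/Q) Σ_j V'(i−1, j+1) · K_stack(i−1,j+1,i,j)
                     · K_stack(i,j,i+1,j−1) · V(i+1, j−1)

summed over both pairing orientations of i, where V is the interior and
V' the exterior partial partition function and K_stack a stack Boltzmann
factor. The 1/Q normalization makes each term the joint probability that
the three stacked pairs coexist, so 0 ≤ P_i ≤ P(i paired) and
P_1 = P_N = 0 identically.

Arithmetic is plain float64 without rescaling, which bounds practical
partition lengths at roughly 300 nt (an overflow raises a clear error).
Windowed profiles (`window_profile`) cut at most `window` nucleotides
with the site at position window//2 + 1, clamped at the ends; the
package's own demonstrations use windows of ~44 nt on stem-loop
fixtures, a scale at which pure-Python O(n³) recursions run in
milliseconds. The exhaustive enumerator is guarded at 22 nt; oracle
comparisons use lengths 10–16, where ensembles have 10¹–10³ structures.

## Optical melting analysis

Melting curves follow the two-state model with linear upper/lower
baselines. The duplex fraction comes from the exact equilibrium
quadratic; molecularity enters through a = 4 (non-self-complementary)
or a = 1 (self-complementary), giving 1/T_M = (R/ΔH°)·ln(C_T/a) + ΔS°/ΔH°.
The nonlinear curve fit is parameterized by (ΔH°, T_M) rather than
(ΔH°, ΔS°) to break their near-perfect correlation, with three enthalpy
starts (−50, −80, −120 kcal/mol) and the best sum of squares kept; a fit
is rejected ("no transition") when the fitted T_M leaves the measured
range or the transition amplitude is under five times the residual
noise. The T_M⁻¹ vs ln(C_T/a) analysis is an unweighted least-squares
line; free energies used downstream always come from these linear fits.
T_M values are reported in °C at C_T = 10⁻⁴ M by convention. Two-state
consistency requires the curve-fit and T_M-plot enthalpies to agree
within 15 %. Per-experiment uncertainty uses the conservative 4 % of
|ΔG°37| convention; sums of terms propagate as σ² = Σ (n_i σ_i)².

Loop-motif increments subtract reference stabilities: dangling ends and
terminal mismatches from self-complementary duplexes carrying the motif
twice (hence the factor 2), hairpin loops by subtracting the stem's
stacks, interior loops by additionally subtracting duplex initiation and
the symmetry term.

## Stack-parameter regression

For each fully helical duplex the fixed terms (Watson–Crick/G-U stacks,
duplex initiation, terminal A-U penalties, symmetry correction) are
subtracted from the experimental ΔG°37, and the residual is regressed on
integer counts of the 15 m6A-U stack contexts (canonical key: the
lexicographically smaller strand-reading direction; self-complementary
duplexes are walked along the single written strand against its reverse
register, counting each stack twice). Estimation is unweighted ordinary
least squares via statsmodels; uncertainties are the standard errors of
the regression. Terminal m6A-U pairs contribute nothing in the
production model; `include_terminal=True` adds the diagnostic column
whose fitted value is expected to be statistically indistinguishable
from zero. Rank deficiency is reported with the unresolvable columns; a
duplex with no m6A stack context is rejected.

## The synthetic study

`m6afold.synth` regenerates the entire experimental workflow from the
package's own model, so nothing external is needed to exercise any code
path. Its conditions are fixed design choices:

* **32-duplex database**: fourteen 8-mer frame helices each embedding one
  m6A dinucleotide plus a 6U/UA-context duplicate, fourteen longer
  helices with one to three methylations and wobble-flanked contexts,
  two helices with a single terminal m6A-U pair (these break an
  orientation-parity degeneracy that would otherwise make the 15-column
  design rank-14), and a helix-end test pair sharing every stack but
  ending on m6A-U vs C-G. The design matrix has full rank 15 with every
  context observed.
* **Synthetic truth**: the model's duplex energies, plus effects the
  model deliberately omits and a study would still observe — a real
  +0.13 kcal/mol per terminal m6A-U pair (recovered by the diagnostic
  column, dropped by the production model), +0.23 kcal/mol for the
  methylated hairpin-loop motif and +0.33 kcal/mol for the tandem G-m6A
  interior loop (both below their propagated uncertainties, which is why
  the loop tables keep analogous-A values).
* **Measurement emulation**: each duplex receives a per-sample systematic
  error of 2 % of |ΔG°37| (half the conservative 4 % convention,
  matching its definition as twice the mean inter-method difference),
  then nine melting curves at 0.1 mM–1 µM with 0.003 a.u. absorbance
  noise and a generating enthalpy drawn from ΔH° = (6–8.5)·ΔG°37; each
  curve is re-fitted and the T_M plot gives the working stability. Motif
  experiments use a 0.08 kcal/mol observation error, the repeatability of
  a nine-concentration analysis. Reference experimental stabilities for
  the GGACU consensus duplex (−16.19 unmethylated, −15.45 doubly
  methylated, kcal/mol) are synthetic reconstructions anchored to
  published optical-melting results.
* **Folding fixtures**: stem-loops with the GGACU consensus inside the
  stem and three or four seeded mismatches in the complementary arm, so
  the site is buried with intermediate probability and methylation
  visibly shifts the ensemble (methylation can only lower the site's
  buried probability in this design, since every methylated-stack
  increment is destabilizing and the dangle/mismatch bonuses reward the
  unpaired state). Synthetic S1/V1 tracks draw Poisson counts with rates
  tied to the ensemble pairing probability.

What the generator does **not** emulate: genuine model error of the
nearest-neighbor functional form across chemistries, salt dependence,
non-two-state melting, degradation or concentration-determination error
structure, and transcriptome-scale sequence context (real windows of
800 nt around thousands of sites; the demonstrations here use eight
~24-nt fixtures). Tests passing on this synthetic world therefore verify
the machinery — fits, propagation, dynamic programs, extraction
arithmetic — not the field accuracy of the parameters on real RNA.

## Numerical and design choices

* Canonical m6A character is `6`; `M` (and lowercase, and `T`→`U`) are
  normalized on every input path.
* Stacks and interior-loop tables satisfy exact strand-reversal
  symmetry and are tested exhaustively. Terminal-mismatch and dangle
  tables have no such symmetry: their motifs are single-strand-orientated,
  and the published values are asymmetric.
* The coaxial discontinuous-backbone increment is a sequence-independent
  −2.1 kcal/mol.
* OLS coverage: with 32 observations and 15–16 parameters, ±2 SE covers
  ≈94 % of coefficient draws (t with ~17 degrees of freedom), which the
  recovery tests assert as ≥90 %.
* Seeds: every stochastic fixture takes an explicit seed and is
  byte-reproducible; the reproduction script derives all of its
  randomness from `--seed`.

## Known limitations

37 °C only (no m6A enthalpies); no pseudoknots, suboptimal-structure
enumeration or stochastic sampling; coaxial stacking only in the
evaluator, not in the structure search; G-U stacks are the 2004 table
values; PARS 5'-attribution bias is documented, not modelled; partition
lengths are float-range-limited (~300 nt) in this pure-Python
implementation.
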