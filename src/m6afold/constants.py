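"""Physical constants shared across the package.

All free energies are standard folding free energy changes at 37 degC
(kcal/mol). The package deliberately has no temperature dependence beyond
the two-state melting module: enthalpy tables for the modified alphabet are
not part of the model.
"""

#: Gas constant, kcal/(mol*K)
R_KCAL = 1.9872e-3

#: Folding temperature, K (37 degC)
T37 = 310.15

#: R*T at 37 degC, kcal/mol
RT37 = R_KCAL * T37
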