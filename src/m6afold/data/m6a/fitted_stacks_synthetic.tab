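# m6afold table: fitted_stacks (synthetic reference)
# Synthetic reconstruction of the 15 m6A-U helix stack parameters:
# analogous-A stacks plus methylation increments anchored to
# published m6A optical-melting summary values.
# units: kcal/mol at 37 C
# columns: pair1 pair2 dG37   (canonical context keys)
6U 6U   -0.30   # analog -1.10
6U AU   -1.10   # analog -1.10
6U CG   -1.82   # analog -2.08
6U GC   -2.02   # analog -2.24
6U GU   -0.85   # analog -1.40
6U U6    1.45   # analog -0.93
6U UA   -0.62   # analog -0.93
6U UG   -0.20   # analog -0.60
AU U6   -0.64   # analog -0.93
CG U6   -1.87   # analog -2.11
GC U6   -1.79   # analog -2.35
GU U6   -0.92   # analog -1.30
U6 U6   -0.53   # analog -1.33
U6 UA   -0.95   # analog -1.33
U6 UG   -0.58   # analog -1.00
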