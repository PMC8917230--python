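# name: m6A
# RNA extended with N6-methyladenosine, encoded '6' ('M' accepted on input).
# m6A pairs only with U; the methylamino group does not support G pairing.
nucleotides A C G U 6
alias M 6
alias T U
pair A U
pair G C
pair G U
pair 6 U
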