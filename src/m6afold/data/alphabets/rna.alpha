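# name: rna
# Standard RNA folding alphabet: Watson-Crick plus G-U wobble pairs.
nucleotides A C G U
alias T U
pair A U
pair G C
pair G U
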