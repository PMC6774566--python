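# Blood-abundant genes excluded from fusion consideration (category A).
# Globin loci and T-cell receptor loci; glob-style patterns, case-insensitive.
# Edit freely or supply your own list with --abundant-list.
HBA1
HBA2
HBB
HBD
HBE1
HBG1
HBG2
HBM
HBQ1
HBZ
TRA*
TRB*
TRG*
TRD*
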