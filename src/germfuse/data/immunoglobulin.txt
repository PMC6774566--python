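# Immunoglobulin loci (category F, potential immune diversity).
# Glob-style patterns, case-insensitive.
IGH*
IGK*
IGL*
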