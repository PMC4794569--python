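# Two-reader HEp-2 IIF concordance table: 589 wells independently
# reported by two senior immunologists in a multi-centre ANA reading
# study. Rows = reader 2, columns = reader 1; counts of wells.
# Fixture version 1.
label,negative,homogeneous,fine_speckled,coarse_speckled,nucleolar,centromere,nuclear_dots
negative,117,6,10,5,3,0,0
homogeneous,5,110,15,3,1,0,0
fine_speckled,26,22,49,24,1,0,0
coarse_speckled,23,4,20,67,0,0,0
nucleolar,1,0,0,0,38,0,0
centromere,0,0,0,0,0,31,0
nuclear_dots,0,0,0,0,1,0,7
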