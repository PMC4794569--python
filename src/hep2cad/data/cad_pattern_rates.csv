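# Published per-class pattern confusion rates (percent) of a HEp-2 CAD
# system against a gold-standard reference. Rows = reference class,
# columns = CAD call. The 'other' class had no reference examples.
# Fixture version 1.
label,homogeneous,fine_speckled,coarse_speckled,nucleolar,centromere,nuclear_dots,other
homogeneous,81.1,9.5,6.8,2.7,0.0,0.0,0.0
fine_speckled,6.5,54.8,16.1,19.4,3.2,0.0,0.0
coarse_speckled,0.0,9.6,80.8,3.8,3.8,1.9,0.0
nucleolar,3.3,10.0,0.0,86.7,0.0,0.0,0.0
centromere,3.4,3.4,0.0,3.4,89.7,0.0,0.0
nuclear_dots,0.0,0.0,16.7,0.0,0.0,83.3,0.0
other,0.0,0.0,0.0,0.0,0.0,0.0,0.0
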