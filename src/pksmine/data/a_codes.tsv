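# Editable A-domain binding-pocket ("specificity code") table: 10 residues
# read at the packaged anchor columns of the A exemplar, following the
# standard nonribosomal code convention (invariant Asp first, Lys last).
# Calls use nearest-code Hamming distance with a 1-mismatch tolerance.
substrate	code
glycine	DILQLGLIWK
alanine	DLLFGIAVLK
serine	DVWHLSLIDK
valine	DFWNIGMVHK
leucine	DAWFLGNVVK
threonine	DFWNIGMVHR
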