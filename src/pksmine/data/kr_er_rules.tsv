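# Editable stereochemistry fingerprint rules for KR and ER domains.
# KR motif = residues at the 4 packaged anchor columns (catalytic-region
# diagnostic positions): an LDD motif in the first three marks a B-type KR
# (D-configured hydroxyl), a Trp at the fourth marks an A-type KR
# (L-configured hydroxyl).  ER motif = 1 residue: Tyr present predicts the
# (S)-configured methyl branch, its absence the (R) configuration.
# Patterns are Python regular expressions matched against the full motif;
# the first matching rule for a class wins.  These follow the standard
# published fingerprints; edit this table to change or extend the rules.
rule_id	domain_class	pattern	call
kr_b_lld	KR	LDD[^-]	B_type
kr_a_trp	KR	[^-][^-][^-]W	A_type
er_s_tyr	ER	Y	S_config
er_r_other	ER	[^Y-]	R_config
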