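# Synthetic exemplar bundle: anchor columns are 0-based positions in the
# exemplar sequence; min_score is the per-class Smith-Waterman detection
# threshold calibrated on shuffled-composition nulls (max + 3 sd, rounded up).
exemplar_id	domain_class	anchor_columns	min_score
KS_ref	KS	120	80
AT_ref	AT	95,96,97,98,99	78
DH_ref	DH		88
ER_ref	ER	80	80
KR_ref	KR	60,61,62,93	90
MT_ref	MT		77
ACP_ref	ACP		74
C_ref	C		89
A_ref	A	40,55,70,85,100,115,130,145,160,175	89
PCP_ref	PCP		62
TE_ref	TE		92
P450_ref	P450		105
MONOOX_ref	MONOOX		77
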