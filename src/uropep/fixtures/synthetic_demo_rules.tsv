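# SYNTHETIC demonstration protease-specificity rules (NOT curated biology).
# Format: one rule per row; columns P4..P1 (N-side of the scissile bond) and
# P1p..P4p (prime side) each hold an allowed-residue set or '*' (wildcard).
# A peptide terminus matches a rule when every non-wildcard position is
# satisfied by the corresponding residue of its reconstructed octamer.
protease	P4	P3	P2	P1	P1p	P2p	P3p	P4p
TRYP_LIKE	*	*	*	KR	*	*	*	*
GLUC_LIKE	*	*	*	E	*	*	*	*
PRO_X	*	*	P	*	*	*	*	*
XAA_GLY	*	*	*	*	G	*	*	*
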