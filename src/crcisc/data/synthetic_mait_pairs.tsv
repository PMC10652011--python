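# Synthetic stand-in reference table of paired MAIT TCR alpha/beta CDR3 amino-acid
# sequences. These are fabricated sequences with the canonical MAIT-like shape
# (semi-invariant TRAV1-2/TRAJ33-style alpha paired with variable betas); they play the
# role of a functionally validated riboflavin-reactive pair list for identity scoring.
pair_id	cdr3_alpha_aa	cdr3_beta_aa
MAIT01	CAVMDSNYQLIW	CASSEFGQGFYEQYF
MAIT02	CAVMDSNYQLIW	CASSPLAGGTDTQYF
MAIT03	CAVRDSNYQLIW	CASSEVSGTGELFF
MAIT04	CAVMDSSYKLIW	CASSQDRGQETQYF
MAIT05	CAVSDSNYQLIW	CASSLGWGDEQFF
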