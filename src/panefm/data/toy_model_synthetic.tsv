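# Synthetic reconstruction of the 14-reaction toy pan-reactome (unit
# stoichiometries).  The published reaction table was not redistributable;
# this transcription was rebuilt from the toy network's described structure
# and is validated against its three published summary counts: 9 minimal
# functional sets in the rich environment, 208 growth-supporting
# presence/absence environments, and {R5, R9, R12, R13, R14} required for
# biomass production everywhere.
# stoichiometry: semicolon-separated met:coef pairs, negative = consumed.
reaction_id	stoichiometry	lower_bound	upper_bound
R1	M1_e:-1;M1_i:1;M2_i:1	0	1000
R2	M2_e:-1;M1_i:1	0	1000
R3	M5_i:-1;M3_i:1	0	1000
R4	M3_i:-1;M1_i:1	0	1000
R5	M5_e:-1;M5_i:1	0	1000
R6	M6_e:-1;M6_i:1	0	1000
R7	M8_e:-1;M8_i:1;M4_e:1	0	1000
R8	M9_e:-1;M8_i:1	0	1000
R9	M5_i:-1;M1_i:-1;M9_i:1	0	1000
R10	M2_i:-1;M2_e:1	0	1000
R11	M6_i:-1;M7_e:-1;M8_i:1;M3_e:1	0	1000
R12	M9_i:-1;M10_i:1	0	1000
R13	M9_i:-1;M11_i:1	0	1000
R14	M9_i:-1;M8_i:-1;M12_i:1	0	1000
biomass	M10_i:-1;M11_i:-1;M12_i:-1	0	1000
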