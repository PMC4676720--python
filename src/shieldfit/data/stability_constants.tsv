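# EGTA stability constants on the concentration scale, referenced to I = 0.1 M, 20 C (293.15 K).
# Transcribed from critically evaluated chelator compilations (Martell & Smith / NIST SRD 46 lineage)
# as adopted by Ca2+-buffer calculators; see docs/methods.md for the selection rationale.
# pkas are ligand protonation constants, pKa1 first (strictly decreasing).
# dh values are reaction enthalpies in kJ/mol for van't Hoff temperature adjustment.
ligand	metal	log_k_ml	log_k_mhl	pkas	metal_charge	ligand_charge	ref_ionic_strength	ref_temperature_k	dh_ml_kj	dh_pkas_kj	source
EGTA	Ca	10.97	5.30	9.54,8.93,2.66,2.00	2	-4	0.1	293.15	-33.1	-24.3,-19.7,0.0,0.0	chelator compilation (NIST-46-derived)
EGTA	Mg	5.28	3.37	9.54,8.93,2.66,2.00	2	-4	0.1	293.15	21.0	-24.3,-19.7,0.0,0.0	chelator compilation (NIST-46-derived)
EGTA	Ba	8.41	4.73	9.54,8.93,2.66,2.00	2	-4	0.1	293.15	-20.1	-24.3,-19.7,0.0,0.0	chelator compilation (NIST-46-derived)
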