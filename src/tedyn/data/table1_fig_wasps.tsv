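species	group	oviposition_site	r	mu	genome_size	te_length	te_count	te_family_count	te_content
Platyscapa_corneri	pollinator	inside	0.0049	2.43e-09	304.37	18.23	57619	56	5.99
Eupristina_koningsbergeri	pollinator	inside	0.0051	2.55e-09	318.36	48.99	113791	54	15.39
Wiebesia_pumilae	pollinator	inside	0.0047	2.37e-09	319.91	25.07	80474	55	7.84
Dolichoris_vasculosae	pollinator	inside	0.0050	2.48e-09	286.21	8.02	30895	50	2.80
Kradibia_gibbosae	pollinator	inside	0.0052	2.60e-09	230.30	7.66	42828	53	3.33
Ceratosolen_fusciceps	pollinator	inside	0.0053	2.66e-09	235.18	9.06	57250	52	3.85
Sycobia_sp2	NPFW	outside	0.0048	2.40e-09	621.39	235.27	673913	63	37.86
Philotrypesis_tridentata	NPFW	outside	0.0049	2.45e-09	398.61	170.35	401464	65	42.74
Apocrypta_bakeri	NPFW	outside	0.0051	2.57e-09	198.59	27.51	146704	61	13.85
Sycophaga_agraensis	NPFW	outside	0.0048	2.40e-09	246.14	45.80	114334	60	18.61
Sycophila_sp2	NPFW	outside	0.0043	2.16e-09	288.59	80.51	252000	63	27.90
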