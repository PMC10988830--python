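# Bundled 10-variant reference table (printed ddG values in kcal/mol,
# codon substitution probabilities, and published prediction labels).
# table: binding = interface set, stability = domain-core set
label	table	prediction	wt_codon	mut_codon	base_replacement	ddg_stability	ddg_binding	probability
E1299W	binding	Deleterious	GAG	TGG	GAG→TGG	0.46	4.24	0.00037
C1387W	binding	Deleterious	TGC	TGG	TGC→TGG	-1.71	16.22	0.00388
T1430W	binding	Deleterious	ACG	TGG	ACG→TGG	-1.06	6.82	0.00076
A1464W	binding	Deleterious	GCC	TGG	GCC→TGG	-0.12	14.12	0.00041
T1394A	binding	Benign	ACT	GCT	ACT→GCT	0.55	1.90	0.03483
E1304G	stability	Deleterious	GAA	GGA	GAA→GGA	3.92	1.00	0.01115
Y1318G	stability	Deleterious	TAC	GGC	TAC→GGC	5.46	1.02	0.00094
Y1383A	stability	Deleterious	TAT	GCT	TAT→GCT	3.83	0.98	0.00163
G1453W	stability	Deleterious	GGC	TGG	GGC→TGG	3.94	4.57	0.00065
S1403F	stability	Benign	TCC	TTC	TCC→TTC	1.45	0.97	0.00750
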