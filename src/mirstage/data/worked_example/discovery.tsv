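mirna_id	fold_change	q_value
miR-99a-5p	1.81	5.68e-4
miR-99a-3p	1.66	9.65e-3
miR-34c-5p	2.36	2.43e-6
miR-34c-3p	2.53	1.54e-2
miR-31-5p	2.77	5.98e-4
miR-31-3p	4.59	5.23e-4
miR-218-5p	1.91	9.55e-4
miR-214-5p	1.84	2.23e-6
miR-214-3p	2.84	2.12e-8
miR-204-5p	2.27	4.73e-2
miR-145-5p	1.91	1.93e-5
miR-143-5p	1.68	7.92e-6
miR-143-3p	1.76	4.44e-5
miR-133a-3p	1.65	1.11e-2
miR-129-2-3p	3.12	8.55e-3
miR-100-3p	2.43	8.47e-3
let-7g-3p	1.58	4.64e-2
let-7f-1-3p	1.83	3.24e-4
let-7e-3p	1.65	6.27e-4
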