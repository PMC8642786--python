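precursor_id	fold_change	p_value
mir-99a	1.49	3.27e-2
mir-34c	2.06	7.75e-6
mir-31	1.76	3.96e-2
mir-218	1.60	9.40e-4
mir-214	1.29	4.40e-2
mir-204	2.55	1.96e-3
mir-145	1.79	3.35e-4
mir-143	1.40	2.51e-2
mir-133a	2.28	1.32e-4
mir-129-2	1.75	2.07e-2
mir-100	1.43	2.11e-2
let-7g	1.35	8.10e-4
let-7f-1	1.81	3.87e-3
let-7e	1.92	2.38e-5
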