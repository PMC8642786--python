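precursor_id	mature_id
mir-99a	miR-99a-5p
mir-99a	miR-99a-3p
mir-34c	miR-34c-5p
mir-34c	miR-34c-3p
mir-31	miR-31-5p
mir-31	miR-31-3p
mir-218	miR-218-5p
mir-218	miR-218-3p
mir-214	miR-214-5p
mir-214	miR-214-3p
mir-204	miR-204-5p
mir-204	miR-204-3p
mir-145	miR-145-5p
mir-145	miR-145-3p
mir-143	miR-143-5p
mir-143	miR-143-3p
mir-133a	miR-133a-5p
mir-133a	miR-133a-3p
mir-129-2	miR-129-5p
mir-129-2	miR-129-2-3p
mir-100	miR-100-5p
mir-100	miR-100-3p
let-7g	let-7g-5p
let-7g	let-7g-3p
let-7f-1	let-7f-5p
let-7f-1	let-7f-1-3p
let-7e	let-7e-5p
let-7e	let-7e-3p
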