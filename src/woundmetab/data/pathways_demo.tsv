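pathway_id	name	node_a	node_b
ARG	Arginine biosynthesis	C00025	C00064
ARG	Arginine biosynthesis	C00025	C00327
ARG	Arginine biosynthesis	C00327	C00062
CYSMET	Cysteine and methionine metabolism	C00073	C00019
CYSMET	Cysteine and methionine metabolism	C00019	C00021
CYSMET	Cysteine and methionine metabolism	C00019	C00170
CYSMET	Cysteine and methionine metabolism	C00021	C00155
CYSMET	Cysteine and methionine metabolism	C00021	C00212
CYSMET	Cysteine and methionine metabolism	C00155	C02291
CYSMET	Cysteine and methionine metabolism	C00155	C00073
CYSMET	Cysteine and methionine metabolism	C02291	C00491
CYSMET	Cysteine and methionine metabolism	C00051	
ARGPRO	Arginine and proline metabolism	C00062	C00148
ARGPRO	Arginine and proline metabolism	C00148	C01157
ARGPRO	Arginine and proline metabolism	C00062	C00327
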