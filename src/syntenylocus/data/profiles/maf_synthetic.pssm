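NAME	Maf
LENGTH	30
ALPHABET	ACDEFGHIKLMNPQRSTVWY
THRESHOLD	13.824210
PROVENANCE	synthetic seed alignment (25 seqs, 15% divergence, seed 202)
-1.169925	-1.169925	-0.169925	3.289507	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-0.169925	-1.169925	-0.169925	-1.169925	-1.169925
-1.169925	-1.169925	0.415037	-1.169925	-0.169925	-1.169925	3.152003	-0.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925
-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	3.353637	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-0.169925	-1.169925	-1.169925
-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	0.415037	-0.169925	-1.169925	3.152003	-1.169925	-1.169925	-0.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925
-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	3.353637	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925
-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	3.353637	-0.169925	-1.169925	-1.169925
-1.169925	-1.169925	-0.169925	-1.169925	3.152003	-1.169925	-0.169925	-0.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925
-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	3.473931	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925
-1.169925	-1.169925	3.222392	-0.169925	-1.169925	0.415037	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925
-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	3.473931	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925
-0.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	3.289507	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925
-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	3.289507	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-0.169925	-0.169925	-1.169925	-1.169925
-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	3.353637	-1.169925	-0.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925
-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	3.353637	-0.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925
-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-0.169925	3.353637	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925
-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	3.152003	-0.169925	-0.169925	-1.169925
-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	3.415037	-1.169925
-1.169925	-1.169925	-1.169925	-0.169925	3.353637	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925
-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	3.473931	-1.169925
-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	3.353637	-1.169925
-1.169925	-1.169925	-1.169925	-1.169925	0.415037	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	3.353637	-0.169925	-1.169925
-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	3.222392	-0.169925	-1.169925	0.415037	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-0.169925	-1.169925
-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	3.353637	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-0.169925	-1.169925	-1.169925	-1.169925
-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	0.415037	-1.169925	-1.169925	-0.169925	-0.169925	-1.169925	-1.169925	3.289507	-1.169925	-1.169925	-1.169925	-1.169925
-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	3.473931	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925
-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-0.169925	3.222392	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925
0.415037	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	3.353637	-1.169925
-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	3.415037	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925
-0.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	3.222392	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-0.169925	-0.169925
-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-1.169925	-0.169925	-1.169925	-1.169925	-0.169925	3.353637	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925	-1.169925
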