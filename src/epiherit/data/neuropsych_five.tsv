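name	H2	E_P	G_SNP	G_CNV	G_A_reported	note
ASD	0.924	0.0	0.17	0.2	0.924
ADHD	0.763	0.2	0.28	0.02	0.468
Bipolar disorder	0.676	0.27	0.25		0.333
Depression	0.579	0.362	0.21		0.192	source table prints hybrid residual 0.207 (explained 64.2%, residual 35.8%); the bundled components reproduce 0.206 (64.4%, 35.6%) from unrounded-source arithmetic
Schizophrenia	0.562	0.254	0.23	0.04	0.308
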