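	HRN	HRM	HRD
HRN	3	0	0
HRM	1	3	0
HRD	2	0	11
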