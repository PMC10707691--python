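sample_id	academic_class	myriad_band	myriad_score
1	HRD-H	D	59
2	HRD-M	D	54
3	HRD-H	D	69
4	HRD-H	D	74
5	HRD-H	D	61
6	HRD-H	D	56
7	HRD-N	N	22
8	HRD-H	D	56
9	HRD-H	D	64
10	HRD-M	D	50
11	HRD-H	D	61
12	HRD-N	N	14
13	HRD-H	D	95
14	HRD-M	D	51
15	HRD-H	D	66
16	HRD-H	D	57
17	ND	D	45
18	HRD-H	D	67
19	HRD-H	N	41
20	HRD-M	D	52
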