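# On-target and off-target indel percentages, cultured cells.
# Fibroblasts: IPLV-delivered nuclease, paired mock. HSPC: IPLV-delivered nuclease, paired mock.
# differential = pct_indels_zfn - pct_indels_mock as printed; ND = not determined.
site_id	sample	pct_indels_mock	pct_indels_zfn	differential
On-target	Fibroblasts	0.05	18.02	17.97
Off-target 1	Fibroblasts	0.66	0.73	0.07
Off-target 2	Fibroblasts	0.10	0.21	0.11
Off-target 3	Fibroblasts	0.02	0.11	0.09
Off-target 4	Fibroblasts	0.11	0.10	-0.01
Off-target 5	Fibroblasts	0.06	0.14	0.08
Off-target 6	Fibroblasts	0.76	0.98	0.22
Off-target 7	Fibroblasts	0.00	0.01	0.01
Off-target 8	Fibroblasts	0.52	1.03	0.51
Off-target 9	Fibroblasts	0.01	1.35	1.34
On-target	HSPCs	0.08	0.60	0.52
Off-target 1	HSPCs	0.08	0.53	0.45
Off-target 2	HSPCs	0.08	0.16	0.08
Off-target 3	HSPCs	0.00	0.00	0.00
Off-target 4	HSPCs	0.02	0.03	0.01
Off-target 5	HSPCs	0.04	0.03	-0.01
Off-target 6	HSPCs	0.69	0.70	0.01
Off-target 7	HSPCs	0.01	ND	ND
Off-target 8	HSPCs	0.29	0.18	-0.11
Off-target 9	HSPCs	0.00	ND	ND
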