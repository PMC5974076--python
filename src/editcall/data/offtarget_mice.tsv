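# On-target and off-target indel percentages, transplanted primary mice.
# The mock column is a shared background sample (one mouse's spleen, IDLV group);
# treated samples are thymus and spleen CD8 T-cells of one responder (IPLV group).
# differential = pct_indels_zfn - pct_indels_mock as printed; ND = not determined.
site_id	sample	pct_indels_mock	pct_indels_zfn	differential
On-target	Mouse thymus	1.23	46.03	44.80
Off-target 1	Mouse thymus	3.92	3.04	-0.88
Off-target 2	Mouse thymus	0.13	0.07	-0.07
Off-target 3	Mouse thymus	0.01	0.04	0.03
Off-target 4	Mouse thymus	0.05	0.05	0.00
Off-target 5	Mouse thymus	0.12	0.05	-0.07
Off-target 6	Mouse thymus	2.14	1.91	-0.23
Off-target 7	Mouse thymus	0.01	0.00	-0.01
Off-target 8	Mouse thymus	0.83	0.67	-0.16
Off-target 9	Mouse thymus	0.05	0.39	0.34
Off-target 10	Mouse thymus	0.95	0.76	-0.19
On-target	Mouse spleen CD8	1.23	68.06	66.83
Off-target 1	Mouse spleen CD8	3.92	3.91	-0.01
Off-target 2	Mouse spleen CD8	0.13	0.14	0.01
Off-target 3	Mouse spleen CD8	0.01	0.02	0.01
Off-target 4	Mouse spleen CD8	0.05	0.04	-0.01
Off-target 5	Mouse spleen CD8	0.12	0.08	-0.04
Off-target 6	Mouse spleen CD8	2.14	1.92	-0.22
Off-target 7	Mouse spleen CD8	0.01	0.00	-0.01
Off-target 8	Mouse spleen CD8	0.83	0.74	-0.10
Off-target 9	Mouse spleen CD8	0.05	0.04	-0.01
Off-target 10	Mouse spleen CD8	0.95	0.83	-0.12
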