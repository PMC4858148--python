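mirna	fold_change	log2_fc	p_value
gga-miR-3536	16.48	4.04	< 0.001
gga-miR-499-3p	13.73	3.78	< 0.001
gga-miR-24-5p	12.09	3.60	< 0.001
gga-miR-27b-5p	6.04	2.60	0.005
gga-miR-2188-5p	5.83	2.54	< 0.001
gga-miR-193b-5p	5.60	2.49	< 0.001
gga-miR-3528	5.37	2.42	< 0.001
gga-miR-451	4.25	2.09	< 0.001
gga-miR-1736-3p	4.21	2.07	< 0.001
gga-miR-365-5p	3.85	1.94	< 0.001
gga-miR-144-3p	3.83	1.94	< 0.001
gga-miR-1552-3p	3.57	1.84	0.007
gga-miR-92-5p	3.30	1.72	< 0.001
gga-miR-365-3p	3.14	1.65	< 0.001
gga-miR-193b-3p	2.95	1.56	< 0.001
gga-miR-221-5p	2.75	1.46	0.011
gga-miR-142-3p	2.58	1.37	< 0.001
gga-miR-183	2.38	1.25	< 0.001
gga-miR-29b-3p	2.32	1.22	< 0.001
gga-miR-101-5p	2.30	1.20	< 0.001
gga-miR-1451-5p	2.16	1.11	< 0.001
gga-miR-142-5p	2.15	1.11	< 0.001
gga-miR-19a-3p	2.00	1.00	< 0.001
gga-miR-216b	0.50	-1.01	< 0.001
gga-miR-216a	0.49	-1.02	0.024
gga-miR-1664-3p	0.46	-1.13	< 0.001
gga-miR-375	0.45	-1.16	< 0.001
gga-miR-193a-3p	0.41	-1.30	0.003
gga-miR-193a-5p	0.38	-1.40	< 0.001
gga-miR-449c-5p	0.34	-1.54	< 0.001
gga-miR-31-5p	0.33	-1.60	0.002
gga-miR-217-5p	0.24	-2.04	< 0.001
gga-miR-20a-3p	0.24	-2.09	< 0.001
gga-miR-133a-3p	0.24	-2.05	< 0.001
gga-miR-155	0.22	-2.15	< 0.001
gga-miR-460b-5p	0.17	-2.53	< 0.001
gga-miR-29c-3p	0.15	-2.70	< 0.001
gga-miR-9-5p	0.15	-2.70	< 0.001
gga-miR-19b-3p	0.15	-2.80	< 0.001
gga-miR-460b-3p	0.09	-3.45	< 0.001
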