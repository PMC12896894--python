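gene_name	gene_id	length	mw_kda	pi	aliphatic_index	instability_index	gravy	subcellular	gpi_anchored	gpi_likelihood
AcXYLP1	Achrdv1x19g206970	179	17.47	7.50	93.30	45.22	0.677	Cell membrane	Yes	0.638
AcXYLP2	Achrdv1x07g069520	177	17.44	6.03	99.27	56.50	0.601	Cell membrane	Yes	0.371
AcXYLP3	Achrdv1x06g063540	178	17.32	6.50	91.12	50.40	0.626	Cell membrane	Yes	0.689
AcXYLP4	Achrdv1x11g116950	153	16.22	6.02	93.07	41.20	0.653	Cell membrane	no	0.893
AcXYLP5	Achrdv1x21g226030	196	19.40	3.79	82.81	57.65	0.610	Cell membrane	Yes	0.508
AcXYLP6	Achrdv1x28g317560	200	19.33	4.18	95.15	57.60	0.465	Cell membrane	Yes	0.312
AcXYLP7	Achrdv1x20g214560	182	18.77	8.42	81.54	51.36	0.203	Cell membrane	Yes	0.203
AcXYLP8	Achrdv1x29g328370	193	19.91	9.11	80.88	51.51	0.111	Cell membrane	Yes	0.396
AcXYLP9	Achrdv1x23g257850	210	21.87	5.62	98.52	58.16	0.380	Cell membrane	Yes	0.400
AcXYLP10	Achrdv1x24g268350	171	17.22	7.48	79.30	59.38	0.224	Cell membrane	Yes	0.340
AcXYLP11	Achrdv1x03g038080	171	17.10	5.04	77.60	59.03	0.177	Cell membrane	Yes	0.297
AcXYLP12	Achrdv1x08g081880	192	20.36	7.47	95.52	47.82	0.131	Cell membrane	Yes	0.276
AcXYLP13	Achrdv1x15g166120	196	21.10	8.35	88.11	60.28	0.037	Cell membrane	Yes	0.396
AcXYLP14	Achrdv1x26g299150	172	17.96	8.54	80.00	44.22	-0.033	Cell membrane	Yes	0.437
AcXYLP15	Achrdv1x24g268360	179	17.98	7.51	79.61	76.75	0.331	Cell membrane	Yes	0.552
AcXYLP16	Achrdv1x28g319270	187	19.64	5.67	93.85	36.23	0.117	Cell membrane	Yes	0.509
AcXYLP17	Achrdv1x20g218800	195	19.89	7.46	81.13	44.07	0.040	Cell membrane	Yes	0.607
AcXYLP18	Achrdv1x07g077000	194	20.62	5.06	79.95	36.03	0.134	Cell membrane	Yes	0.397
AcXYLP19	Achrdv1x26g288760	182	18.65	7.58	97.64	62.15	0.355	Cell membrane	Yes	0.496
AcXYLP20	Achrdv1x28g318050	195	20.13	8.93	97.54	64.15	0.303	Cell membrane	Yes	0.495
AcXYLP21	Achrdv1x13g145110	188	19.28	6.69	80.53	45.24	0.169	Cell membrane	no	0.385
AcXYLP22	Achrdv1x17g183400	208	21.09	8.15	91.54	60.73	0.527	Cell membrane	Yes	0.663
AcXYLP23	Achrdv1x17g183410	197	19.32	5.05	87.72	50.93	0.444	Cell membrane	Yes	0.369
AcXYLP24	Achrdv1x24g268370	202	20.50	7.51	89.01	54.57	0.417	Cell membrane	Yes	0.804
AcXYLP25	Achrdv1x11g123850	159	16.92	6.78	93.84	40.77	0.236	Cell membrane	Yes	0.469
AcXYLP26	Achrdv1x15g163330	143	14.90	4.77	83.29	40.95	0.424	Cell membrane	Yes	0.663
AcXYLP27	Achrdv1x14g154760	149	15.35	7.45	94.30	41.05	0.330	Cell membrane	Yes	0.638
AcXYLP28	Achrdv1x16g174090	193	20.08	6.52	78.39	56.22	0.125	Cell membrane	Yes	0.281
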