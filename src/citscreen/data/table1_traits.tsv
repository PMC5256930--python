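trait	mean_bb	se_bb	mean_bc	se_bc	mean_cc	se_cc	n	anova_p	differences
Body weight at 1 week (g)	3.98	0.09	4.11	0.09	4.02	0.09	5	0.64	NA
Body weight at 3 weeks (g)	7.48	0.26	7.72	0.26	7.55	0.26	5	0.80	NA
Body weight at 6 weeks (g)	21.16	0.48	21.89	0.48	21.40	0.48	5	0.56	NA
Body weight at 10 weeks (g)	25.32	0.46	26.85	0.46	27.16	0.46	5	0.035	C/C ≥ B/C ≥ B/B
Body weight at 14 weeks (g)	27.03	0.45	29.24	0.45	29.39	0.45	5	0.0052	C/C ≥ B/C > B/B
Weight gain at 1-3 weeks (g)	3.50	0.18	3.61	0.18	3.53	0.18	5	0.90	NA
Weight gain at 3-6 weeks (g)	13.67	0.34	14.17	0.34	13.85	0.34	5	0.60	NA
Weight gain at 6-10 weeks (g)	4.16	0.33	4.96	0.33	5.76	0.33	5	0.016	C/C ≥ B/C ≥ B/B
Weight gain at 10-14 weeks (g)	1.71	0.18	2.38	0.18	2.23	0.18	5	0.056	NA
Total body length (cm)	17.40	0.05	17.60	0.05	17.55	0.05	5	0.048	B/C ≥ C/C ≥ B/B
Tail length (cm)	8.29	0.04	8.38	0.04	8.30	0.04	5	0.28	NA
Head-body length (cm)	9.11	0.04	9.23	0.04	9.26	0.04	5	0.096	NA
Inguinal WAT weight (g)	0.296	0.015	0.272	0.015	0.250	0.015	5	0.13	NA
Epididymal WAT weight (g)	0.301	0.013	0.302	0.013	0.251	0.013	5	0.029	B/C ≥ B/B ≥ C/C
Total WAT weight (g)	0.597	0.027	0.574	0.027	0.502	0.027	5	0.071	NA
Lungs weight (g)	0.146	0.003	0.154	0.003	0.156	0.003	5	0.12	NA
Liver weight (g)	1.162	0.031	1.214	0.031	1.234	0.031	5	0.27	NA
Spleen weight (g)	0.057	0.005	0.071	0.005	0.062	0.005	5	0.130	NA
Kidneys weight (g)	0.337	0.011	0.375	0.011	0.358	0.011	5	0.098	NA
Testes weight (g)	0.201	0.005	0.178	0.005	0.187	0.005	5	0.017	B/B ≥ C/C ≥ B/C
Total-C (mg/g)	59.96	3.13	59.43	3.13	55.73	3.13	5	0.60	NA
CM-C (mg/g)	0.42	0.06	0.45	0.06	0.59	0.06	5	0.16	NA
VLDL-C (mg/g)	3.11	0.21	3.33	0.21	2.83	0.21	5	0.28	NA
LDL-C (mg/g)	5.63	0.25	5.48	0.25	4.67	0.25	5	0.037	B/B ≥ B/C ≥ C/C
HDL-C (mg/g)	50.79	2.91	50.18	2.91	47.64	2.91	5	0.73	NA
Total-TG (mg/g)	34.78	3.35	35.10	3.35	35.03	3.35	5	1.00	NA
CM-TG (mg/g)	3.26	0.76	3.51	0.76	5.44	0.76	5	0.13	NA
VLDL-TG (mg/g)	16.66	1.88	17.55	1.88	16.74	1.88	5	0.93	NA
LDL-TG (mg/g)	13.04	0.87	11.97	0.87	10.89	0.87	5	0.25	NA
HDL-TG (mg/g)	1.82	0.11	2.06	0.11	1.95	0.11	5	0.32	NA
% Tail length	47.62	0.19	47.59	0.19	47.26	0.19	5	0.37	NA
% Head-body length	52.38	0.19	52.41	0.19	52.74	0.19	5	0.37	NA
% Inguinal WAT weight	1.08	0.05	0.93	0.05	0.85	0.05	5	0.030	B/B ≥ B/C ≥ C/C
% Epididymal WAT weight	1.10	0.05	1.03	0.05	0.85	0.05	5	0.010	B/B ≥ B/C ≥ C/C
% Total WAT weight	2.18	0.10	1.96	0.10	1.70	0.10	5	0.019	B/B ≥ B/C ≥ C/C
% Lungs weight	0.54	0.01	0.53	0.01	0.53	0.01	5	0.36	NA
% Liver weight	4.30	0.10	4.15	0.10	4.19	0.10	5	0.57	NA
% Spleen weight	0.21	0.01	0.24	0.01	0.21	0.01	5	0.26	NA
% Kidneys weight	1.24	0.03	1.28	0.03	1.22	0.03	5	0.28	NA
% Testes weight	0.74	0.01	0.61	0.02	0.64	0.01	5	0.000069	B/B > C/C ≥ B/C
% CM-C	0.70	0.09	0.79	0.09	1.05	0.09	5	0.056	NA
% VLDL-C	5.16	0.42	5.75	0.42	5.04	0.42	5	0.49	NA
% LDL-C	9.40	0.52	9.45	0.52	8.33	0.52	5	0.27	NA
% HDL-C	84.74	0.95	84.01	0.95	85.57	0.95	5	0.53	NA
% CM-TG	9.39	1.32	9.89	1.32	15.05	1.32	5	0.019	C/C > B/C ≥ B/B
% VLDL-TG	46.92	1.65	48.47	1.65	47.38	1.65	5	0.80	NA
% LDL-TG	38.34	2.05	34.89	2.05	31.75	2.05	5	0.12	NA
% HDL-TG	5.35	0.59	6.77	0.59	5.81	0.59	5	0.26	NA
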