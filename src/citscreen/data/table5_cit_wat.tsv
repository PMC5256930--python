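trait	gene	p2	p3	p4	label	p3_marginal
Body weight at 10 weeks (g)	Ifih1	0.14	NA	NA		False
Body weight at 14 weeks (g)	Ifih1	0.062	NA	NA		False
Weight gain at 6-10 weeks (g)	Ifih1	0.0027	0.015	0.0031	Reactive	False
Total body length (cm)	Ifih1	0.10	NA	NA		False
Epididymal WAT weight (g)	Ifih1	0.068	NA	NA		False
Testes weight (g)	Ifih1	0.23	NA	NA		False
LDL-C (mg/g)	Ifih1	0.047	0.66	0.54		False
% Testes weight	Ifih1	0.14	NA	NA		False
% Inguinal WAT weight	Ifih1	0.055	NA	NA		False
% Epididymal WAT weight	Ifih1	0.11	NA	NA		False
% Total WAT weight	Ifih1	0.076	NA	NA		False
% CM-TG	Ifih1	0.024	0.29	0.030	Independent	False
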