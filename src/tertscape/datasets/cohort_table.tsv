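tumor_type	n_pos	n_neg	n_no_data	n_mut_C250	n_mut_C228	n_wt	n_total
Acute lymphoblastic leukemia	44	0	44	NA	NA	NA	44
Acute myeloid leukemia	14	1	15	NA	NA	NA	15
Adrenocortical carcinoma	1	3	4	NA	NA	NA	4
Breast cancer	80	33	101	0	0	12	113
Cervical cancer	19	5	24	NA	NA	NA	24
Cholangiocarcinoma	10	2	8	0	0	4	12
Colorectal cancer	131	20	133	0	0	18	151
Esophageal carcinoma	4	0	3	0	0	1	4
Glioblastoma	44	8	43	2	3	4	52
Head and neck cancer	9	1	3	0	0	7	10
Leiomyosarcoma	2	5	6	0	0	1	7
Lung cancer	111	26	129	0	0	8	137
Melanoma	16	6	16	1	2	3	22
Multiple myeloma	50	4	54	NA	NA	NA	54
Other CNS tumors	10	25	33	0	0	2	35
Ovarian cancer	44	23	61	0	0	6	67
Pancreatic adenocarcinoma	30	12	35	0	0	7	42
Prostate adenocarcinoma	9	3	10	0	0	2	12
Renal cell carcinoma	15	16	30	0	0	1	31
Sarcoma	7	1	2	0	0	6	8
Skin carcinoma	5	0	3	0	2	0	5
Soft tissue sarcoma	5	10	13	0	0	2	15
Stomach adenocarcinoma	48	5	45	0	0	8	53
Thymoma	3	0	1	0	0	2	3
Thyroid cancer	40	64	101	1	0	2	104
Urothelial carcinoma	4	2	2	0	2	2	6
Uterine corpus endometrial carcinoma	6	3	6	0	0	3	9
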