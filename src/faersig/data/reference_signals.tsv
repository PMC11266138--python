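drug	soc	pt	a	ror	ror_l95	ror_u95	prr	chi2	ic	ic025	ebgm	ebgm05
baloxavir	Injury, poisoning and procedural complications	Off label use	263	5.60	4.80	6.54	3.85	610.84	1.94	1.72	3.82	3.28
baloxavir	Injury, poisoning and procedural complications	Intentional product use issue	203	97.43	81.73	116.14	66.45	11374.74	5.85	5.28	57.57	48.30
baloxavir	Injury, poisoning and procedural complications	Product administered to patient of inappropriate age	15	6.16	3.67	10.33	5.99	62.03	2.57	1.47	5.94	3.54
baloxavir	Injury, poisoning and procedural complications	Medication error	8	6.36	3.15	12.84	6.26	35.10	2.63	1.00	6.21	3.07
baloxavir	Immune system disorders	Anaphylactic shock	12	21.68	12.10	38.84	21.11	222.50	4.35	2.25	20.44	11.41
baloxavir	General disorders and administration site conditions	No adverse event	268	54.84	46.89	64.15	34.14	8015.30	4.97	4.62	31.43	26.87
baloxavir	Psychiatric disorders	Abnormal behaviour	21	12.28	7.89	19.11	11.75	203.40	3.53	2.37	11.54	7.42
baloxavir	Psychiatric disorders	Delirium	5	9.01	3.71	21.89	8.91	34.67	3.14	0.69	8.80	3.62
oseltamivir	Psychiatric disorders	Abnormal behaviour	34	20.08	14.09	28.62	18.68	553.34	4.18	3.14	18.13	12.72
oseltamivir	Psychiatric disorders	Delirium	17	30.44	18.54	49.99	29.36	443.77	4.81	2.83	27.99	17.04
oseltamivir	Skin and subcutaneous tissue disorders	Stevens-Johnson syndrome	11	12.10	6.61	22.14	11.84	107.18	3.54	1.80	11.62	6.35
oseltamivir	Eye disorders	Visual impairment	7	5.77	2.72	12.21	5.70	26.91	2.50	0.79	5.65	2.67
oseltamivir	Eye disorders	Blindness	5	12.67	5.20	30.87	12.54	52.02	3.62	0.85	12.30	5.05
oseltamivir	Eye disorders	Central vision loss	4	1163.80	212.64	6369.79	1153.78	1535.74	8.59	1.13	385.26	70.39
oseltamivir	Eye disorders	Eye movement disorder	4	9.41	3.49	25.39	9.34	29.35	3.20	0.41	9.21	3.41
oseltamivir	Eye disorders	Acute macular outer retinopathy	3	1741.93	180.85	16777.66	1730.67	1296.52	8.76	0.70	433.42	45.00
oseltamivir	Eye disorders	Blindness unilateral	3	37.86	11.73	122.17	37.62	100.42	5.14	0.30	35.38	10.96
oseltamivir	Eye disorders	Conjunctival haemorrhage	3	42.48	13.11	137.67	42.21	112.49	5.30	0.31	39.40	12.16
oseltamivir	Eye disorders	Symblepharon	3	348.38	83.01	1462.04	346.13	645.28	7.76	0.53	216.71	51.64
oseltamivir	Blood and lymphatic system disorders	Leukopenia	10	7.99	4.25	15.01	7.84	59.02	2.95	1.39	7.75	4.12
oseltamivir	Blood and lymphatic system disorders	Normocytic anaemia	4	166.25	54.52	506.98	164.83	506.62	7.00	0.96	128.42	42.11
oseltamivir	Blood and lymphatic system disorders	Lymphocytosis	3	42.48	13.11	137.67	42.21	112.49	5.30	0.31	39.40	12.16
oseltamivir	Vascular disorders	Shock	5	5.61	2.31	13.59	5.56	18.55	2.46	0.41	5.51	2.27
oseltamivir	Vascular disorders	Shock haemorrhagic	4	31.45	11.45	86.36	31.18	110.90	4.89	0.76	29.64	10.79
oseltamivir	Cardiac disorders	Supraventricular tachycardia	4	13.60	5.03	36.82	13.49	45.25	3.72	0.55	13.21	4.88
oseltamivir	Renal and urinary disorders	Incontinence	3	42.48	13.11	137.67	42.21	112.49	5.30	0.31	39.40	12.16
oseltamivir	Renal and urinary disorders	Kidney enlargement	3	48.38	14.85	157.66	48.07	127.67	5.47	0.33	44.45	13.64
oseltamivir	Respiratory, thoracic and mediastinal disorders	Acute respiratory distress syndrome	7	7.82	3.69	16.59	7.72	40.49	2.93	1.02	7.63	3.60
oseltamivir	Respiratory, thoracic and mediastinal disorders	Pleural effusion	6	5.77	2.57	12.97	5.71	23.15	2.50	0.63	5.67	2.52
oseltamivir	Respiratory, thoracic and mediastinal disorders	Lung disorder	5	7.87	3.24	19.11	7.80	29.27	2.95	0.62	7.71	3.17
oseltamivir	Respiratory, thoracic and mediastinal disorders	Obliterative bronchiolitis	5	45.55	18.25	113.70	45.07	199.90	5.39	1.20	41.88	16.78
oseltamivir	Respiratory, thoracic and mediastinal disorders	Aphonia	3	60.06	18.23	197.86	59.68	156.88	5.76	0.35	54.18	16.45
oseltamivir	Respiratory, thoracic and mediastinal disorders	Haemothorax	3	66.99	20.21	222.11	66.56	173.71	5.90	0.36	59.78	18.03
oseltamivir	Respiratory, thoracic and mediastinal disorders	Hypercapnia	3	20.98	6.61	66.63	20.85	54.74	4.33	0.20	20.16	6.35
oseltamivir	Respiratory, thoracic and mediastinal disorders	Obstructive airways disorder	3	10.75	3.42	33.79	10.68	25.87	3.39	0.03	10.51	3.34
oseltamivir	Respiratory, thoracic and mediastinal disorders	Oropharyngeal oedema	3	96.77	28.41	329.64	96.15	242.14	6.37	0.40	82.56	24.23
oseltamivir	Respiratory, thoracic and mediastinal disorders	Pulmonary fibrosis	3	37.06	11.49	119.48	36.82	98.30	5.12	0.29	34.67	10.75
oseltamivir	Respiratory, thoracic and mediastinal disorders	Pulmonary necrosis	3	870.96	145.19	5224.71	865.34	1036.02	8.44	0.63	346.73	57.80
oseltamivir	Musculoskeletal and connective tissue disorders	Muscular weakness	6	5.84	2.60	13.12	5.78	23.53	2.52	0.64	5.73	2.55
oseltamivir	Musculoskeletal and connective tissue disorders	Musculoskeletal stiffness	4	6.46	2.40	17.37	6.41	18.09	2.67	0.22	6.35	2.36
oseltamivir	Musculoskeletal and connective tissue disorders	Compartment syndrome	3	28.09	8.79	89.81	27.91	74.27	4.74	0.25	26.67	8.34
oseltamivir	Musculoskeletal and connective tissue disorders	Muscle rigidity	3	10.06	3.20	31.62	10.00	23.91	3.30	0.01	9.85	3.13
oseltamivir	Musculoskeletal and connective tissue disorders	Osteopenia	3	16.27	5.15	51.45	16.17	41.56	3.98	0.14	15.76	4.99
oseltamivir	Nervous system disorders	Tremor	12	4.33	2.43	7.69	4.24	29.67	2.08	0.96	4.22	2.37
oseltamivir	Nervous system disorders	Loss of consciousness	9	4.38	2.26	8.49	4.31	22.83	2.10	0.77	4.29	2.21
oseltamivir	Nervous system disorders	Incoherent	4	42.31	15.27	117.24	41.96	149.11	5.29	0.81	39.18	14.14
oseltamivir	Nervous system disorders	Dysgraphia	3	28.09	8.79	89.81	27.91	74.27	4.74	0.25	26.67	8.34
oseltamivir	Nervous system disorders	Muscle contractions involuntary	3	39.58	12.25	127.93	39.33	104.94	5.21	0.30	36.89	11.41
oseltamivir	Nervous system disorders	Neuralgia	3	14.63	4.64	46.18	14.54	36.92	3.83	0.12	14.21	4.50
oseltamivir	Nervous system disorders	Slow response to stimuli	3	40.50	12.52	131.02	40.25	107.35	5.24	0.30	37.69	11.65
oseltamivir	Investigations	Body temperature decreased	6	29.70	13.01	67.81	29.33	156.33	4.81	1.41	27.96	12.25
oseltamivir	Investigations	Influenza A virus test positive	4	211.59	67.13	666.95	209.78	609.53	7.27	0.98	154.10	48.89
oseltamivir	Investigations	Procalcitonin increased	3	35.54	11.04	114.44	35.32	94.29	5.06	0.29	33.34	10.35
oseltamivir	Infections and infestations	Pneumonia	18	3.45	2.15	5.53	3.35	29.86	1.74	0.92	3.34	2.08
oseltamivir	Infections and infestations	Influenza	14	5.33	3.12	9.10	5.20	47.35	2.37	1.28	5.16	3.03
oseltamivir	Infections and infestations	Cytomegalovirus infection reactivation	4	6.53	2.43	17.57	6.48	18.36	2.68	0.23	6.42	2.39
oseltamivir	Infections and infestations	Central nervous system infection	3	79.17	23.61	265.44	78.67	202.45	6.12	0.38	69.35	20.68
oseltamivir	Infections and infestations	Pneumonia necrotising	3	54.43	16.61	178.37	54.08	142.93	5.63	0.34	49.53	15.11
oseltamivir	Infections and infestations	Pneumonia streptococcal	3	60.06	18.23	197.86	59.68	156.88	5.76	0.35	54.18	16.45
oseltamivir	Hepatobiliary disorders	Hepatitis cholestatic	3	23.53	7.39	74.91	23.39	61.80	4.49	0.22	22.52	7.07
oseltamivir	Hepatobiliary disorders	Hepatosplenomegaly	3	10.81	3.44	34.00	10.75	26.06	3.40	0.03	10.57	3.36
oseltamivir	Ear and labyrinth disorders	Ear disorder	3	32.25	10.05	103.52	32.05	85.51	4.93	0.27	30.42	9.48
oseltamivir	Ear and labyrinth disorders	Ear inflammation	3	435.48	97.19	1951.20	432.67	738.31	7.95	0.56	247.67	55.28
oseltamivir	Metabolism and nutrition disorders	Dehydration	15	7.79	4.64	13.07	7.57	84.80	2.90	1.71	7.49	4.46
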