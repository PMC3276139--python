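line	chromosome	start_cM	end_cM	target_size_cM	n_additional	pct_donor	pct_het	hr_stock	core_set
S42IL-101	1H	1.10	13.50	17.7	3	1.1	2.2	715	0
S42IL-102	1H	1.10	98.23	99.2	2	5.2	2.2	673	1
S42IL-103	1H	40.51	89.01	51.1	3	3.0	3.1	968	0
S42IL-157	1H	64.79	90.92	28.6	1	2.3	0.0	i.p.	0
S42IL-104	1H	70.78	78.03	11.9	2	1.9	0.0	703	0
S42IL-105	1H	74.40	90.92	18.5	0	1.2	0.0	293	0
S42IL-158	1H	82.35	90.92	10.5	1	1.9	0.0	i.p.	0
S42IL-141	1H	94.86	127.71	36.3	2	3.0	0.2	504	1
S42IL-143	1H	130.68	173.49	51.8	4	4.2	1.6	1180	1
S42IL-142	1H	188.50	205.07	24.1	0	1.5	0.0	348	1
S42IL-106	2H	22.35	34.31	19.1	0	1.2	0.0	865	1
S42IL-107	2H	34.31	66.78	42.0	1	3.3	0.0	607	0
S42IL-108	2H	34.31	104.81	77.9	1	5.0	0.8	290	1
S42IL-109	2H	63.96	110.84	42.4	0	3.3	0.0	984	1
S42IL-153	2H	108.71	120.83	13.3	3	1.8	0.3	1183	1
S42IL-144	2H	63.96	81.50	21.3	1	1.4	0.0	421	0
S42IL-110	2H	102.66	104.81	5.7	2	1.4	0.0	47	1
S42IL-175	2H	197.39	247.86	52.6	4	3.5	1.8	i.p.	1
S42IL-111	3H	67.01	98.41	34.9	4	3.7	1.9	1062	1
S42IL-154	3H	64.85	144.30	84.8	2	6.9	2.3	i.p.	1
S42IL-155	3H	104.39	144.30	46.7	4	5.5	0.5	i.p.	0
S42IL-112	3H	104.39	161.43	64.3	1	3.8	1.7	1312	1
S42IL-159	3H	154.99	190.87	40.1	1	4.9	0.0	i.p.	0
S42IL-114	3H	138.00	245.49	109.7	3	4.6	3.9	1392	0
S42IL-140	3H	154.99	253.73	101.0	0	6.2	0.0	2096	1
S42IL-115	3H	204.48	255.13	53.7	1	4.3	0.0	791	1
S42IL-160	3H	204.48	221.43	24.8	1	2.5	0.0	i.p.	0
S42IL-113	3H	204.48	239.73	38.3	0	2.4	0.0	396	0
S42IL-161	3H	239.73	253.73	19.1	0	1.2	0.0	i.p.	0
S42IL-116	4H	5.42	47.80	49.1	2	5.3	0.0	724	1
S42IL-117	4H	27.52	64.77	41.2	0	2.6	0.0	529	1
S42IL-145	4H	61.15	64.77	13.8	2	1.6	1.0	1073	0
S42IL-118	4H	61.15	83.58	32.2	1	2.5	0.0	957	1
S42IL-120	4H	61.15	83.58	32.2	0	1.4	0.7	1352	0
S42IL-119	4H	61.15	119.06	69.5	1	4.9	0.0	978	0
S42IL-162	4H	61.15	119.06	69.5	0	4.4	0.0	No	0
S42IL-164	4H	61.15	99.74	49.3	1	3.5	0.0	29	0
S42IL-121	4H	74.11	119.06	50.6	2	3.6	2.1	952	0
S42IL-146	4H	83.58	119.06	43.1	0	1.9	0.6	1322	1
S42IL-166	4H	91.93	119.06	32.0	1	2.5	0.0	No	0
S42IL-123	4H	128.85	172.32	50.5	3	5.5	0.0	1174	1
S42IL-124	4H	171.25	183.54	13.4	2	2.4	0.0	1339	1
S42IL-173	5H	104.73	171.34	74.1	0	4.7	0.0	i.p.	1
S42IL-125	5H	104.73	154.37	56.0	1	3.6	0.5	1095	0
S42IL-147	5H	145.57	154.37	17.3	1	1.1	0.2	i.p.	0
S42IL-126	5H	145.57	200.12	61.8	0	3.9	0.0	400	0
S42IL-176	5H	154.37	234.98	81.8	3	6.3	0.8	No	1
S42IL-127	5H	231.75	276.77	50.0	0	3.2	0.0	1349	1
S42IL-148	6H	3.28	10.73	12.7	2	3.5	0.1	1519	0
S42IL-150	6H	73.90	82.43	13.5	1	1.3	0.0	1167	0
S42IL-152	6H	71.39	82.43	31.2	3	3.5	0.3	i.p.	0
S42IL-149	6H	71.39	82.43	31.2	1	2.4	0.0	1659	0
S42IL-128	6H	71.39	132.23	77.8	1	5.2	0.3	1394	0
S42IL-129	6H	73.90	133.47	63.0	0	3.5	0.5	303	0
S42IL-156	6H	89.78	156.09	72.1	3	8.4	1.5	55	1
S42IL-130	6H	98.66	180.69	83.8	2	4.9	1.1	1250	0
S42IL-131	6H	140.00	180.69	47.2	0	2.3	0.7	1244	1
S42IL-163	6H	137.78	163.56	31.1	2	2.0	0.2	i.p.	0
S42IL-132	6H	160.38	191.46	31.6	0	2.0	0.0	185	0
S42IL-122	6H	180.69	208.13	32.8	3	3.5	1.2	1007	1
S42IL-151	6H	98.66	111.56	16.5	3	2.2	0.7	1419	0
S42IL-133	7H	17.32	51.93	44.0	4	4.9	0.7	302	1
S42IL-134	7H	51.93	107.44	59.1	1	3.7	0.9	1468	1
S42IL-135	7H	101.23	152.29	63.1	0	4.0	0.0	29	1
S42IL-167	7H	101.23	114.58	14.4	1	0.9	0.1	i.p.	0
S42IL-168	7H	101.23	116.68	16.5	2	1.5	1.6	40	0
S42IL-169	7H	101.23	120.92	26.4	2	1.7	0.8	17	0
S42IL-170	7H	114.58	120.92	13.1	0	0.8	0.0	i.p.	0
S42IL-171	7H	116.68	134.43	19.5	1	1.3	0.2	42	0
S42IL-136	7H	134.43	152.29	36.7	2	3.5	0.0	1137	0
S42IL-137	7H	134.43	193.89	66.8	4	8.1	0.2	948	1
S42IL-138	7H	176.37	229.66	65.3	1	4.8	1.1	841	1
S42IL-139	7H	198.70	229.66	31.5	0	2.0	0.0	474	0
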