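mrna	mrna_fc	mrna_fdr	mirna	mirna_fc	mirna_fdr	seed_type	start	end
Hbq1a	3.002	2.57E-07	miR-377-3p	0.592	1.08E-03	7mer-m8	252	258
Rpp21	2.852	2.35E-20	miR-136-5p	0.613	9.18E-06	8mer	3537	3544
Gchfr	2.696	9.55E-06	miR-129-1-3p	0.570	4.18E-04	7mer-m8	298	304
Gchfr	2.696	9.55E-06	miR-129-2-3p	0.590	1.62E-05	7mer-m8	298	304
Gm20390	2.669	2.25E-23	miR-429-3p	0.329	3.53E-12	7mer-m8	3377	3383
Gm20390	2.669	2.25E-23	miR-429-3p	0.329	3.53E-12	8mer	4329	4336
Gm20390	2.669	2.25E-23	miR-429-3p	0.329	3.53E-12	8mer	4714	4721
Gm20390	2.669	2.25E-23	miR-200b-3p	0.375	6.58E-08	7mer-m8	3377	3383
Gm20390	2.669	2.25E-23	miR-200b-3p	0.375	6.58E-08	8mer	4329	4336
Gm20390	2.669	2.25E-23	miR-200b-3p	0.375	6.58E-08	8mer	4714	4721
Gm20390	2.669	2.25E-23	miR-344d-3p	0.741	4.47E-03	7mer-A1	3316	3322
Gm9726	2.627	2.76E-04	miR-29b-3p	0.726	4.41E-03	8mer	326	333
Hist1h4h	2.505	1.18E-15	miR-9-5p	0.753	5.60E-03	7mer-m8	26	32
Serf2	2.421	7.81E-20	miR-200a-3p	0.381	1.24E-13	7mer-m8	213	219
Serf2	2.421	7.81E-20	miR-141-3p	0.458	3.07E-04	7mer-m8	213	219
Serf2	2.421	7.81E-20	let-7f-5p	0.735	8.04E-04	8mer	2110	2117
Serf2	2.421	7.81E-20	let-7b-5p	0.741	6.40E-03	8mer	2110	2117
Serf2	2.421	7.81E-20	let-7c-5p	0.766	9.52E-03	8mer	2110	2117
Mrps16	2.418	2.40E-15	miR-136-5p	0.613	9.18E-06	7mer-m8	86	92
Zfp46	2.409	3.91E-12	miR-129-1-3p	0.570	4.18E-04	7mer-m8	464	470
Zfp46	2.409	3.91E-12	miR-129-2-3p	0.590	1.62E-05	7mer-m8	464	470
Ndufb2	2.368	2.31E-22	miR-429-3p	0.329	3.53E-12	7mer-m8	3896	3902
Ndufb2	2.368	2.31E-22	miR-200b-3p	0.375	6.58E-08	7mer-m8	3896	3902
Esrrb	2.332	7.67E-08	let-7f-5p	0.735	8.04E-04	8mer	617	624
Esrrb	2.332	7.67E-08	let-7b-5p	0.741	6.40E-03	8mer	617	624
Esrrb	2.332	7.67E-08	miR-485-5p	0.753	4.04E-03	7mer-m8	55	61
Esrrb	2.332	7.67E-08	miR-9-5p	0.753	5.60E-03	8mer	2337	2344
Esrrb	2.332	7.67E-08	let-7c-5p	0.766	9.52E-03	8mer	617	624
Polr2f	2.323	2.02E-26	miR-488-3p	0.752	8.56E-03	7mer-m8	485	491
Nme1	2.305	3.32E-21	miR-200a-3p	0.381	1.24E-13	8mer	123	130
Nme1	2.305	3.32E-21	miR-141-3p	0.458	3.07E-04	8mer	123	130
Gm9844	2.296	1.27E-04	miR-129-5p	0.721	1.46E-03	8mer	26	33
Diras1	2.234	1.93E-12	miR-7b-5p	0.715	1.25E-03	7mer-m8	2200	2206
Myl6	2.234	8.56E-15	miR-340-5p	0.741	6.55E-03	7mer-A1	851	857
Psma2	2.174	3.46E-21	miR-132-3p	0.726	6.55E-03	7mer-A1	111	117
Mrpl14	2.172	2.53E-14	miR-340-5p	0.741	6.55E-03	7mer-A1	2823	2829
Ptrhd1	2.170	1.90E-13	miR-181d-5p	0.676	2.00E-04	7mer-m8	2022	2028
Ptrhd1	2.170	1.90E-13	miR-181b-5p	0.680	5.42E-05	7mer-m8	2022	2028
Ptrhd1	2.170	1.90E-13	miR-488-3p	0.752	8.56E-03	8mer	76	83
Dynlt1f	2.169	1.11E-08	miR-29b-3p	0.726	4.41E-03	7mer-A1	215	221
Sod1	2.162	7.65E-13	miR-377-3p	0.592	1.08E-03	7mer-m8	78	84
Cst6	2.158	6.60E-14	miR-377-3p	0.592	1.08E-03	7mer-m8	2027	2033
Cst6	2.158	6.60E-14	miR-181d-5p	0.676	2.00E-04	7mer-m8	2023	2029
Cst6	2.158	6.60E-14	miR-181b-5p	0.680	5.42E-05	7mer-m8	2023	2029
Rpl31	2.153	6.45E-09	miR-653-5p	0.616	4.04E-03	7mer-A1	639	645
Rpl31	2.153	6.45E-09	miR-129-5p	0.721	1.46E-03	8mer	671	678
Tmsb4x	2.126	2.94E-14	miR-183-5p	0.319	3.96E-21	7mer-m8	327	333
Ndufb9	2.104	7.81E-20	miR-200a-3p	0.381	1.24E-13	8mer	2453	2460
Ndufb9	2.104	7.81E-20	miR-141-3p	0.458	3.07E-04	8mer	2453	2460
Ndufb9	2.104	7.81E-20	miR-365-3p	0.654	9.94E-03	7mer-m8	2718	2724
Ndufb9	2.104	7.81E-20	miR-532-5p	0.740	2.06E-03	7mer-m8	3048	3054
Ndufb9	2.104	7.81E-20	miR-340-5p	0.741	6.55E-03	7mer-A1	1850	1856
Ndufb9	2.104	7.81E-20	miR-379-5p	0.752	6.55E-03	7mer-m8	3186	3192
Rps12	2.097	2.19E-06	miR-96-5p	0.235	1.36E-17	7mer-m8	2285	2291
Acot13	2.097	2.94E-07	miR-429-3p	0.329	3.53E-12	7mer-m8	4417	4423
Acot13	2.097	2.94E-07	miR-200b-3p	0.375	6.58E-08	7mer-m8	4417	4423
Acot13	2.097	2.94E-07	miR-653-5p	0.616	4.04E-03	7mer-A1	5139	5145
Acot13	2.097	2.94E-07	miR-181d-5p	0.676	2.00E-04	7mer-m8	4525	4531
Acot13	2.097	2.94E-07	miR-181b-5p	0.680	5.42E-05	7mer-m8	4525	4531
Aamdc	2.094	9.88E-15	miR-485-5p	0.753	4.04E-03	7mer-m8	64	70
Cisd3	2.093	9.98E-20	miR-9-5p	0.753	5.60E-03	7mer-A1	358	364
Tmem151b	2.035	2.86E-07	miR-129-1-3p	0.570	4.18E-04	7mer-m8	2722	2728
Tmem151b	2.035	2.86E-07	miR-129-2-3p	0.590	1.62E-05	7mer-m8	2722	2728
Tmem151b	2.035	2.86E-07	miR-181d-5p	0.676	2.00E-04	7mer-m8	2226	2232
Tmem151b	2.035	2.86E-07	miR-181b-5p	0.680	5.42E-05	7mer-m8	2226	2232
Tmem151b	2.035	2.86E-07	miR-132-3p	0.726	6.55E-03	8mer	339	346
Tmem151b	2.035	2.86E-07	miR-29b-3p	0.726	4.41E-03	7mer-m8	2452	2458
Tmem151b	2.035	2.86E-07	miR-485-5p	0.753	4.04E-03	8mer	2089	2096
Erh	2.031	1.69E-09	miR-181d-5p	0.676	2.00E-04	7mer-m8	118	124
Erh	2.031	1.69E-09	miR-181b-5p	0.680	5.42E-05	7mer-m8	118	124
Tomm5	2.011	4.37E-19	miR-151-3p	0.770	6.36E-03	7mer-m8	383	389
Gosr2	0.374	1.22E-11	miR-27a-3p	1.421	8.66E-04	8mer	94	101
Nkx2-1	0.459	1.19E-03	miR-503-5p	1.581	1.48E-03	7mer-m8	74	80
Prkag1	0.488	8.60E-03	miR-34a-5p	1.941	7.79E-08	7mer-m8	42	48
Prkag1	0.488	8.60E-03	miR-34b-5p	1.893	1.43E-06	7mer-m8	42	48
Lurap1l	0.489	1.18E-06	miR-497a-5p	2.053	3.09E-13	8mer	60	67
Lurap1l	0.489	1.18E-06	miR-503-5p	1.581	1.48E-03	7mer-A1	61	67
Pfn2	0.496	8.36E-09	miR-106b-5p	1.789	9.32E-11	7mer-m8	452	458
Pfn2	0.496	8.36E-09	miR-106b-5p	1.789	9.32E-11	7mer-m8	1197	1203
Zbtb9	0.496	3.34E-05	miR-497a-5p	2.053	3.09E-13	7mer-m8	42	48
Zbtb9	0.496	3.34E-05	miR-497a-5p	2.053	3.09E-13	7mer-m8	45	51
Zbtb9	0.496	3.34E-05	miR-106b-5p	1.789	9.32E-11	8mer	822	829
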