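mrna	mrna_fc	mrna_fdr	mirna	mirna_fc	mirna_fdr	seed_type	start	end
Arf5	4.543	1.01E-24	miR-29b-3p	0.650	4.95E-06	8mer	392	399
Pcolce2	4.447	9.69E-19	miR-340-5p	0.618	2.19E-10	7mer-A1	329	335
Pcolce2	4.447	9.69E-19	miR-146b-5p	0.721	1.68E-04	7mer-A1	3039	3045
Tom1l1	4.011	2.74E-21	miR-340-5p	0.618	2.19E-10	7mer-A1	397	403
Tom1l1	4.011	2.74E-21	miR-340-5p	0.618	2.19E-10	8mer	2622	2629
Tom1l1	4.011	2.74E-21	miR-181b-5p	0.763	2.71E-03	8mer	371	378
Tom1l1	4.011	2.74E-21	miR-142a-5p	0.765	8.25E-03	7mer-A1	2622	2628
Tom1l1	4.011	2.74E-21	miR-181c-5p	0.770	3.26E-03	8mer	371	378
Rasd1	3.629	3.25E-11	miR-377-3p	0.558	4.71E-04	7mer-m8	572	578
Rasd1	3.629	3.25E-11	miR-30c-5p	0.710	2.01E-04	8mer	465	472
Rasd1	3.629	3.25E-11	miR-384-5p	0.735	3.14E-04	8mer	465	472
Pcna	3.195	6.07E-16	miR-137-3p	0.652	9.24E-08	8mer	420	427
Spns1	3.031	1.55E-11	miR-29b-3p	0.650	4.95E-06	8mer	266	273
Ppp2cb	3.022	5.91E-20	miR-183-5p	0.551	2.97E-06	8mer	152	159
Ppp2cb	3.022	5.91E-20	miR-142a-5p	0.765	8.25E-03	7mer-A1	142	148
Steap3	2.857	2.10E-06	miR-377-3p	0.558	4.71E-04	7mer-A1	704	710
Dnajc9	2.787	7.78E-14	miR-132-3p	0.710	1.32E-04	7mer-m8	1040	1046
Rpa1	2.704	2.98E-15	miR-30c-5p	0.710	2.01E-04	7mer-m8	1195	1201
Rpa1	2.704	2.98E-15	miR-384-5p	0.735	3.14E-04	7mer-m8	1195	1201
Rpa1	2.704	2.98E-15	miR-361-5p	0.762	2.72E-03	7mer-m8	591	597
Rpa1	2.704	2.98E-15	miR-361-5p	0.762	2.72E-03	7mer-A1	627	633
Net1	2.675	4.10E-07	miR-340-5p	0.618	2.19E-10	7mer-A1	31	37
Net1	2.675	4.10E-07	miR-135a-5p	0.631	7.96E-09	8mer	831	838
Net1	2.675	4.10E-07	miR-135b-5p	0.645	4.36E-05	8mer	831	838
Gpx4	2.617	1.68E-17	miR-374b-5p	0.549	2.62E-05	7mer-A1	833	839
Ogfod2	2.613	3.97E-11	miR-340-5p	0.618	2.19E-10	8mer	493	500
Sin3a	2.598	2.68E-09	miR-211-5p	0.492	7.97E-12	7mer-m8	870	876
Sin3a	2.598	2.68E-09	miR-183-5p	0.551	2.97E-06	7mer-m8	644	650
Sin3a	2.598	2.68E-09	miR-493-5p	0.699	3.98E-03	7mer-m8	724	730
Sin3a	2.598	2.68E-09	miR-493-5p	0.699	3.98E-03	8mer	840	847
Eif5a	2.561	5.52E-19	miR-495-3p	0.472	8.00E-16	7mer-A1	589	595
Gosr2	2.511	5.84E-16	miR-493-5p	0.699	3.98E-03	8mer	1649	1656
Chst15	2.455	2.63E-07	miR-342-3p	0.704	8.42E-05	8mer	1364	1371
Tmem159	2.443	1.65E-04	miR-135a-5p	0.631	7.96E-09	7mer-m8	607	613
Tmem159	2.443	1.65E-04	miR-135b-5p	0.645	4.36E-05	7mer-m8	607	613
Rab40b	2.414	3.16E-05	miR-211-5p	0.492	7.97E-12	8mer	336	343
Rabl6	2.413	2.15E-08	miR-30c-5p	0.710	2.01E-04	8mer	371	378
Rabl6	2.413	2.15E-08	miR-384-5p	0.735	3.14E-04	8mer	371	378
Id3	2.400	5.82E-11	miR-340-5p	0.618	2.19E-10	7mer-A1	489	495
Htra2	2.381	6.59E-05	miR-410-3p	0.667	4.11E-07	7mer-A1	160	166
Kctd3	2.355	2.23E-08	miR-29b-3p	0.650	4.95E-06	7mer-A1	432	438
Kctd3	2.355	2.23E-08	miR-30c-5p	0.710	2.01E-04	7mer-m8	411	417
Kctd3	2.355	2.23E-08	miR-384-5p	0.735	3.14E-04	7mer-m8	411	417
Atg16l1	2.346	3.04E-12	let-7k	0.615	1.81E-04	7mer-A1	235	241
Atg16l1	2.346	3.04E-12	miR-410-3p	0.667	4.11E-07	8mer	1100	1107
Atg16l1	2.346	3.04E-12	miR-142a-5p	0.765	8.25E-03	7mer-m8	872	878
Srl	2.344	8.98E-04	miR-211-5p	0.492	7.97E-12	8mer	2918	2925
Srl	2.344	8.98E-04	miR-136-5p	0.582	2.87E-08	8mer	818	825
Srl	2.344	8.98E-04	miR-136-5p	0.582	2.87E-08	8mer	4468	4475
Marcksl1	2.271	1.11E-08	miR-23b-3p	0.740	1.75E-03	8mer	576	583
Marcksl1	2.271	1.11E-08	miR-23a-3p	0.755	3.09E-03	8mer	576	583
Ccdc32	2.241	2.68E-07	miR-377-3p	0.558	4.71E-04	7mer-m8	165	171
Prpf19	2.227	2.45E-17	miR-377-3p	0.558	4.71E-04	8mer	2354	2361
Prpf19	2.227	2.45E-17	miR-421-3p	0.701	6.33E-03	8mer	2841	2848
Prpf19	2.227	2.45E-17	miR-203-3p	0.732	7.63E-04	7mer-m8	120	126
Tbc1d8b	2.222	2.86E-03	miR-340-5p	0.618	2.19E-10	8mer	2336	2343
Tbc1d8b	2.222	2.86E-03	miR-142a-5p	0.765	8.25E-03	7mer-m8	1016	1022
Tbc1d8b	2.222	2.86E-03	miR-142a-5p	0.765	8.25E-03	7mer-A1	2336	2342
Kdelr1	2.222	7.47E-08	miR-340-5p	0.618	2.19E-10	7mer-A1	313	319
Kdelr1	2.222	7.47E-08	miR-335-5p	0.637	4.58E-06	7mer-A1	715	721
Gm2a	2.184	1.22E-07	miR-6395	0.682	5.46E-03	8mer	591	598
Zfp622	2.170	1.71E-11	miR-181b-5p	0.763	2.71E-03	8mer	410	417
Zfp622	2.170	1.71E-11	miR-181c-5p	0.770	3.26E-03	8mer	410	417
Gap43	2.163	3.62E-03	miR-23b-3p	0.740	1.75E-03	7mer-m8	433	439
Gap43	2.163	3.62E-03	miR-23a-3p	0.755	3.09E-03	7mer-m8	433	439
Grasp	2.157	9.32E-04	miR-132-3p	0.710	1.32E-04	7mer-m8	668	674
Gpr182	2.134	4.61E-03	miR-30c-5p	0.710	2.01E-04	7mer-A1	2658	2664
Gpr182	2.134	4.61E-03	miR-384-5p	0.735	3.14E-04	7mer-A1	2658	2664
Metap1	2.125	1.20E-06	miR-211-5p	0.492	7.97E-12	7mer-m8	1354	1360
Metap1	2.125	1.20E-06	miR-382-3p	0.528	3.46E-11	7mer-m8	1373	1379
Metap1	2.125	1.20E-06	miR-181b-5p	0.763	2.71E-03	7mer-m8	1334	1340
Metap1	2.125	1.20E-06	miR-142a-5p	0.765	8.25E-03	7mer-m8	1221	1227
Metap1	2.125	1.20E-06	miR-181c-5p	0.770	3.26E-03	7mer-m8	1334	1340
Chid1	2.123	5.05E-07	miR-142a-5p	0.765	8.25E-03	7mer-m8	2673	2679
Tmem184a	2.121	3.51E-03	miR-137-3p	0.652	9.24E-08	8mer	2889	2896
Tmem184a	2.121	3.51E-03	miR-410-3p	0.667	4.11E-07	7mer-A1	3706	3712
Tmem184a	2.121	3.51E-03	miR-493-5p	0.699	3.98E-03	7mer-m8	2883	2889
Tmem184a	2.121	3.51E-03	miR-487b-3p	0.702	4.08E-04	8mer	3684	3691
Htr2c	2.106	2.43E-10	miR-382-3p	0.528	3.46E-11	8mer	1230	1237
Htr2c	2.106	2.43E-10	miR-137-3p	0.652	9.24E-08	8mer	2964	2971
Htr2c	2.106	2.43E-10	miR-23b-3p	0.740	1.75E-03	8mer	1871	1878
Htr2c	2.106	2.43E-10	miR-23a-3p	0.755	3.09E-03	8mer	1871	1878
Alpl	2.103	3.66E-06	miR-211-5p	0.492	7.97E-12	8mer	655	662
Ddah2	2.093	1.58E-08	miR-29b-3p	0.650	4.95E-06	7mer-m8	69	75
Zkscan4	2.087	1.94E-05	miR-29b-3p	0.650	4.95E-06	7mer-A1	390	396
Atg7	2.087	1.98E-05	miR-211-5p	0.492	7.97E-12	8mer	1454	1461
Atg7	2.087	1.98E-05	miR-382-3p	0.528	3.46E-11	7mer-m8	1438	1444
Atg7	2.087	1.98E-05	miR-142a-5p	0.765	8.25E-03	7mer-m8	879	885
Galnt18	2.083	1.04E-04	miR-340-5p	0.618	2.19E-10	7mer-A1	245	251
Thg1l	2.060	1.05E-03	miR-340-5p	0.618	2.19E-10	7mer-A1	280	286
Slc25a18	2.045	5.08E-05	let-7k	0.615	1.81E-04	8mer	106	113
Api5	2.023	3.22E-09	miR-203-3p	0.732	7.63E-04	8mer	1699	1706
Bcl2l1	2.020	8.98E-07	miR-495-3p	0.472	8.00E-16	7mer-A1	1219	1225
Bcl2l1	2.020	8.98E-07	miR-377-3p	0.558	4.71E-04	7mer-m8	1242	1248
Bcl2l1	2.020	8.98E-07	miR-377-3p	0.558	4.71E-04	8mer	1424	1431
Bcl2l1	2.020	8.98E-07	let-7k	0.615	1.81E-04	8mer	947	954
Bcl2l1	2.020	8.98E-07	miR-342-3p	0.704	8.42E-05	7mer-m8	1243	1249
Cat	2.014	3.45E-06	miR-23b-3p	0.740	1.75E-03	8mer	793	800
Cat	2.014	3.45E-06	miR-23a-3p	0.755	3.09E-03	8mer	793	800
Ccdc80	2.011	6.43E-03	miR-29b-3p	0.650	4.95E-06	8mer	213	220
Ccdc80	2.011	6.43E-03	miR-433-3p	0.673	1.45E-05	8mer	1243	1250
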