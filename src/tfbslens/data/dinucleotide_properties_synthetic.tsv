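attribute	AA	AC	AG	AT	CA	CC	CG	CT	GA	GC	GG	GT	TA	TC	TG	TT
nn_free_energy	-1.000	-1.440	-1.280	-0.880	-1.450	-1.840	-2.170	-1.280	-1.300	-2.240	-1.840	-1.440	-0.580	-1.300	-1.450	-1.000
nn_enthalpy	-7.900	-8.400	-7.800	-7.200	-8.500	-8.000	-10.600	-7.800	-8.200	-9.800	-8.000	-8.400	-7.200	-8.200	-8.500	-7.900
nn_entropy	-22.200	-22.400	-21.000	-20.400	-22.700	-19.900	-27.200	-21.000	-22.200	-24.400	-19.900	-22.400	-21.300	-22.200	-22.700	-22.200
syn01	36.278	34.690	35.275	23.812	24.768	34.365	28.009	31.184	37.170	35.728	29.186	32.552	25.324	24.881	36.857	34.277
syn02	16.740	20.335	18.320	20.051	18.373	18.501	18.362	19.751	18.088	19.780	19.063	17.511	18.473	17.044	20.006	18.952
syn03	15.197	13.346	15.116	12.862	14.645	12.962	14.486	13.341	12.825	11.609	11.770	14.800	15.706	15.167	16.009	12.342
syn04	20.556	18.482	21.532	19.509	17.825	19.966	18.138	18.956	19.724	21.581	20.382	20.349	17.751	19.356	20.957	19.303
syn05	36.693	32.533	41.770	32.764	37.254	36.381	31.871	35.966	22.315	38.212	48.665	31.634	22.020	42.643	34.644	36.884
syn06	25.706	18.648	29.061	27.128	35.097	24.295	26.515	31.436	28.639	27.325	25.972	25.260	24.425	28.463	22.225	23.413
syn07	33.045	36.022	33.092	30.646	30.292	33.750	34.426	31.063	31.052	31.920	32.848	33.295	30.679	30.894	35.702	32.263
syn08	1.520	0.969	8.235	8.370	3.656	6.504	-1.702	4.642	6.305	5.185	4.362	1.282	3.767	1.981	4.815	0.747
syn09	-0.193	1.036	-0.442	-0.125	-1.302	3.962	1.309	3.126	1.334	1.591	1.338	-0.051	0.488	1.608	-1.145	-2.255
syn10	3.259	18.443	6.449	19.944	7.744	19.010	10.583	8.886	8.916	13.492	10.519	3.208	16.994	17.421	13.670	11.982
syn11	-5.451	0.023	-1.167	-3.713	0.045	-1.213	0.507	-1.296	0.868	3.522	-2.995	1.810	1.097	-0.719	-0.927	-0.314
syn12	29.701	31.151	29.300	27.665	29.434	31.913	33.485	28.447	26.675	31.789	32.137	28.983	33.538	28.458	29.371	33.035
syn13	8.699	22.292	20.609	16.210	25.158	20.940	18.212	16.630	20.246	12.360	19.328	18.291	11.844	16.488	14.516	17.333
syn14	35.527	33.489	34.482	33.823	33.901	28.148	33.857	35.741	38.264	34.620	35.499	29.987	30.025	37.412	32.688	36.446
syn15	28.352	24.896	25.966	34.451	32.401	30.849	32.574	26.448	22.105	26.654	30.089	29.547	24.670	29.325	31.755	34.755
syn16	36.266	39.460	35.522	35.425	37.045	37.146	36.325	35.665	37.979	36.280	39.480	37.837	39.353	33.520	38.183	36.441
syn17	32.535	32.065	32.453	32.100	33.677	33.014	32.508	33.919	33.733	32.311	33.409	33.269	31.803	31.864	32.352	32.451
syn18	29.513	28.088	29.834	27.476	27.150	27.738	27.683	28.985	30.571	28.466	26.093	30.342	27.689	26.779	25.536	28.412
syn19	28.360	23.869	27.011	24.917	20.843	31.404	22.343	27.463	21.891	31.567	19.023	30.058	22.013	20.245	26.547	26.101
syn20	8.184	11.625	-1.404	11.397	2.355	9.902	-0.339	0.150	8.277	11.613	2.356	5.865	7.090	4.042	3.099	6.640
syn21	1.586	0.110	-2.313	-1.459	-2.991	-2.601	-1.870	-5.811	-0.072	-4.395	-1.931	-4.632	-3.119	-4.630	0.123	-0.313
syn22	43.339	36.052	32.099	39.387	39.464	46.430	37.862	38.138	42.382	41.539	39.007	46.603	40.249	33.966	39.819	40.987
syn23	9.939	10.592	8.561	12.755	9.978	9.086	11.278	11.348	11.454	10.441	12.224	10.651	10.641	7.211	8.364	11.530
syn24	14.515	20.799	21.400	13.279	11.389	19.107	20.631	3.486	17.044	24.650	16.492	16.183	24.906	13.625	25.458	21.420
syn25	2.489	-2.630	-0.228	5.073	2.989	-1.074	-1.879	0.297	-0.097	0.535	0.898	-1.541	-2.407	-1.409	-2.878	-1.539
syn26	40.490	31.591	24.026	34.642	33.243	32.557	35.421	33.261	32.947	25.371	43.022	31.429	30.998	27.035	19.035	33.172
syn27	7.317	7.945	4.323	3.703	7.225	12.021	10.404	5.876	7.946	6.876	4.273	1.165	4.724	6.596	11.139	4.876
syn28	-0.072	1.207	0.272	1.905	0.593	1.605	0.655	0.444	0.639	0.589	0.389	0.700	1.311	-0.098	0.801	2.043
syn29	-0.641	-1.228	-2.511	-0.364	-7.047	-3.207	-5.054	-4.028	-0.073	-4.688	-2.539	-5.680	1.031	-1.450	-8.213	-4.010
syn30	14.244	9.492	10.021	14.094	10.062	8.040	9.646	15.684	9.219	15.167	5.974	10.640	10.528	12.881	11.078	14.315
syn31	13.421	19.684	14.333	21.101	24.764	22.508	16.255	13.726	19.599	25.962	18.773	20.704	18.306	16.087	17.225	19.954
syn32	6.566	7.072	7.853	5.043	7.906	8.165	5.670	6.303	6.375	5.399	3.816	6.838	5.459	6.448	6.537	6.359
syn33	35.956	39.148	35.503	38.021	35.486	38.555	36.227	36.221	33.627	38.142	36.633	39.832	36.890	37.722	36.421	35.694
syn34	5.078	8.217	4.882	5.161	0.418	3.199	4.318	3.385	10.496	4.887	3.713	6.435	9.103	1.788	5.402	6.912
syn35	27.083	22.377	23.874	25.461	23.308	21.956	24.255	30.119	16.178	27.325	33.674	23.137	25.374	24.443	32.589	21.888
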