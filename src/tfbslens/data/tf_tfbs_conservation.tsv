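tf_id	tf_score	tfbs_score
T00035	0.510	22.689
T02068	0.229	37.695
T01581	0.281	22.469
T00036	0.323	53.477
T02256	0.000	19.975
T01649	0.490	21.440
T00040	0.156	17.661
T02336	0.458	18.020
T01675	0.479	16.642
T00045	0.417	24.431
T02338	0.635	43.785
T01710	0.312	19.878
T00100	0.000	8.600
T02513	0.510	19.355
T01737	0.396	19.207
T00105	0.250	23.436
T02689	0.573	11.751
T01788	0.000	42.591
T00112	0.000	26.139
T02758	0.000	24.052
T01806	0.281	9.876
T00113	0.281	31.947
T02769	0.406	31.273
T01828	0.396	15.416
T00123	0.323	37.325
T02905	0.417	29.244
T01836	0.552	38.128
T00133	0.531	40.426
T03828	0.000	30.425
T01862	0.365	27.131
T00137	0.000	22.547
T03978	0.344	16.819
T01863	0.365	27.131
T00140	0.469	80.516
T04076	0.333	20.941
T01873	0.406	19.462
T00149	0.417	24.994
T04096	0.406	41.469
T01888	0.365	20.913
T00163	0.500	36.319
T04139	0.396	32.720
T01944	0.240	26.854
T00167	0.615	40.211
T04169	0.292	20.608
T01964	0.000	36.555
T00168	0.312	12.591
T04255	0.229	9.579
T02016	0.396	11.973
T00204	0.000	43.157
T04292	0.458	32.288
T02057	0.333	10.183
T00207	0.000	23.891
T04323	0.469	30.400
T02072	0.406	5.871
T00241	0.458	35.887
T04337	0.417	8.588
T02083	0.000	22.700
T00250	0.000	38.958
T04345	0.281	17.885
T02142	0.146	22.509
T00311	0.000	21.446
T04362	0.344	16.418
T02251	0.292	40.375
T00330	0.250	19.700
T04651	0.219	24.345
T02327	0.271	81.746
T00331	0.438	25.084
T04673	0.000	16.867
T02344	0.521	22.483
T00337	0.000	11.789
T04674	0.000	14.984
T02349	0.417	11.981
T00368	0.208	25.903
T04675	0.240	10.487
T02361	0.000	26.080
T00423	0.208	18.856
T04682	0.000	19.150
T02450	0.396	12.598
T00490	0.000	42.650
T04683	0.521	26.489
T02529	0.250	31.583
T00525	0.354	37.525
T04684	0.521	29.356
T02532	0.000	9.291
T00529	0.542	5.670
T04728	0.938	2.200
T02772	0.323	33.126
T00539	0.000	23.310
T04734	0.448	33.173
T02983	0.156	12.375
T00581	0.156	16.629
T04742	0.417	29.900
T03388	0.000	17.450
T00594	0.406	18.237
T05040	0.417	10.977
T03389	0.604	18.979
T00625	0.000	30.061
T05887	0.208	12.650
T03461	0.490	12.826
T00630	0.417	9.392
T05990	0.167	9.142
T04176	0.427	22.757
T00641	0.417	28.149
T06429	0.333	19.271
T04203	0.458	24.991
T00646	0.312	25.800
T08251	0.479	18.206
T04347	0.271	24.125
T00647	0.312	27.887
T08292	0.188	19.371
T04368	0.406	12.612
T00671	0.271	10.249
T08300	0.240	25.765
T04446	0.458	1.591
T00719	0.000	32.340
T00017	0.167	18.741
T04668	0.073	13.053
T00721	0.000	24.300
T00018	0.000	8.178
T04669	0.562	24.492
T00759	0.604	44.722
T00104	0.260	14.491
T04670	0.615	28.587
T00764	0.354	19.933
T00111	0.365	38.400
T04671	0.604	28.089
T00794	1.000	18.030
T00131	0.542	37.864
T04811	0.000	14.562
T00851	0.000	30.779
T00138	0.000	10.669
T04849	0.354	28.104
T00857	0.490	23.217
T00152	0.000	13.035
T05012	0.167	51.522
T00874	0.448	48.698
T00244	0.490	32.023
T05840	0.625	48.409
T00878	0.448	58.069
T00273	0.615	13.368
T05943	0.417	22.448
T00885	0.396	15.250
T00278	0.385	19.934
T06029	0.396	20.694
T00899	0.417	34.042
T00377	0.490	23.438
T06585	0.438	24.253
T00900	0.417	29.490
T00378	0.458	5.421
T06593	0.198	32.085
T00902	0.000	30.319
T00402	0.250	11.518
T08231	0.490	14.017
T00915	0.427	15.628
T00422	0.167	13.413
T08291	0.344	18.350
T00929	0.469	16.593
T00425	0.167	15.035
T00042	0.146	10.674
T00968	0.490	28.308
T00437	0.000	42.280
T00108	0.000	17.824
T00997	0.073	23.077
T00454	0.438	27.733
T00109	0.000	7.500
T01005	0.792	28.543
T00505	0.771	27.210
T00124	0.312	42.912
T01009	0.792	33.484
T00526	0.312	43.133
T00132	0.531	33.659
T01042	0.750	18.733
T00528	0.219	38.886
T00164	0.510	38.254
T01071	0.500	14.414
T00595	0.406	22.510
T00183	0.354	21.642
T01122	0.000	11.302
T00644	0.365	24.060
T00258	0.167	20.208
T01313	0.219	27.573
T00648	0.312	19.429
T00333	0.229	24.129
T01345	0.542	27.789
T00651	0.156	22.926
T00369	0.219	23.012
T01346	0.000	34.134
T00677	0.333	12.273
T00371	0.000	20.978
T01427	0.656	20.220
T00680	0.000	33.917
T00372	0.458	23.436
T01428	0.208	32.483
T00681	0.000	24.983
T00424	0.177	16.045
T01462	0.260	37.833
T00684	0.000	43.609
T00459	0.219	14.155
T01468	0.302	15.041
T00694	0.250	16.028
T00535	0.375	30.000
T01481	0.562	20.503
T00702	0.208	35.793
T00599	0.375	40.421
T01493	0.260	27.513
T00752	0.604	53.710
T00691	0.000	22.778
T01527	0.458	29.300
T00765	0.365	12.164
T00754	0.583	44.405
T01528	0.448	29.592
T00859	0.490	19.629
T00853	0.000	23.131
T01542	0.510	30.648
T00877	0.396	45.574
T00856	0.479	16.747
T01553	0.542	25.917
T00930	0.448	24.136
T01040	0.479	14.921
T01580	0.292	18.325
T00989	0.469	35.417
T01049	0.531	19.961
T01599	0.375	19.287
T01112	0.000	17.350
T01050	0.271	20.600
T01607	0.448	40.100
T01147	0.448	29.662
T01349	0.458	38.760
T01673	0.677	23.779
T01201	0.396	6.845
T01562	0.531	13.891
T01795	0.417	13.877
T01211	0.219	19.882
T01921	0.219	23.153
T01804	0.604	45.070
T01311	0.469	14.534
T02115	0.396	47.292
T01823	0.000	15.839
T01331	0.531	33.655
T02288	0.000	27.853
T01839	0.417	28.932
T01332	0.479	33.209
T02290	0.417	17.006
T01840	0.417	29.820
T01429	0.302	25.000
T02716	0.479	11.258
T01853	0.500	23.999
T01441	0.156	62.155
T02815	0.427	1.021
T01920	0.000	13.056
T01445	0.469	71.685
T03257	0.000	15.213
T01948	0.240	28.606
T01483	0.365	21.781
T03258	0.000	15.307
T01950	0.208	24.200
T01526	0.469	14.751
T03458	0.490	8.353
T01951	0.208	24.200
T01543	0.500	26.750
T04297	0.448	17.736
T01973	0.188	11.157
T01554	0.542	17.850
T04761	0.521	20.942
T01975	0.000	24.591
T01574	0.260	26.200
T05026	0.000	7.374
T02054	0.406	15.031
T01579	0.531	23.187
T05137	0.365	10.673
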