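feature_id	fold_change	p_value
8061	18.96	2.14e-06
9812	4.26	7.49e-08
8807	2.98	1.57e-05
10877	2.81	8.45e-06
6074	2.51	2.20e-06
5893	2.45	2.32e-05
5722	2.41	1.24e-05
797	2.37	3.12e-05
3750	2.37	1.48e-05
10903	2.17	4.02e-05
2927	2.13	1.30e-06
118	2.07	1.33e-05
8273	1.97	1.27e-10
8698	1.95	1.55e-06
851	1.92	5.58e-06
1739	1.90	2.18e-05
964	1.87	1.06e-08
9237	1.80	9.96e-05
5784	1.78	1.49e-12
9799	1.77	2.44e-08
3629	1.74	5.36e-05
9473	1.71	5.79e-05
6529	-1.77	4.72e-08
10990	-1.93	5.66e-06
10449	-2.16	1.97e-05
11834	-2.27	1.55e-05
8815	-2.86	2.44e-07
4388	-2.94	9.76e-05
7379	-3.56	5.55e-05
5143	-3.75	3.18e-05
6738	-6.94	8.49e-13
4218	-13.28	8.57e-09
7355	-14.15	4.94e-05
2363	-18.93	1.74e-07
4062	-19.21	1.04e-07
6079	-24.25	4.79e-06
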