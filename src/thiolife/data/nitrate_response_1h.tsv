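feature_id	fold_change	p_value
10845	33.97	3.70e-09
5509	21.55	2.24e-05
1269	15.88	1.57e-06
9771	11.40	2.07e-06
8807	2.48	1.29e-05
9812	2.05	9.89e-05
8060	-1.70	2.72e-25
6696	-1.72	3.99e-08
6529	-1.83	8.64e-05
7967	-1.85	2.76e-05
10741	-1.85	2.68e-05
3375	-2.17	1.28e-06
6519	-2.84	1.91e-06
11662	-7.78	3.62e-05
10272	-9.18	8.87e-06
5289	-11.03	9.50e-06
2363	-12.20	6.72e-06
9695	-12.78	4.16e-05
10482	-16.20	7.56e-05
7355	-16.21	2.35e-07
2545	-27.35	7.21e-09
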