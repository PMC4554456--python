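sample_id	total_cfu	b1_cfu	b2_cfu	d_cfu	yjaa_cfu
E1_0000	78382.7257033966	2879.0685070882273	50735.35638454532	9657.914308472411	56402.961454855955
E1_0001	5288305.709803345	218671.35265348895	3825749.384143993	439131.8647935422	3654376.4266130677
E1_0002	5252.2982797434315	181.94843528849432	3460.9836559599717	624.4214278853622	4083.5346963732336
E2_0000	2012928.7106092854	1439808.2732717653	122785.96106108312	550382.9754469045	244061.66932497197
E2_0001	859553.8129160722	588078.320527087	36592.041610632565	173488.1459961563	69396.27770429252
E2_0002	1912423.2375264305	1005398.9343523973	52887.41222624302	492050.30548748106	225939.97181390488
E3_0000	32590585.617780846	7124502.205997223	1780123.612861682	5269967.153522863	11732762.924307223
E3_0001	15903558.26988278	4858795.108127992	944503.2247753455	2782548.0632827473	5896175.736806506
E3_0002	27374596.8350252	4782792.570910653	1821454.2325905806	3645333.827952307	12128530.053190028
E4_0000	43067528.29289083	1046422.7407589841	50205078.9161924	386834.578329797	44768643.370557174
E4_0001	10177672.692968182	103412.04263395692	9868521.725192016	325586.6459947551	10044797.04350207
E4_0002	19273806.20506965	487683.1146094277	16346464.546994103	311385.0550237378	18017810.890905432
E5_0000	129489101.90352646	11627879.081889845	14739859.932211228	17398833.0839258	50901396.92602625
E5_0001	83580199.80410823	11760609.352734582	9906795.812993186	12421517.27227404	29209045.595987465
E5_0002	133562748.23307103	12581102.005920649	13647654.03523748	21137825.478262767	51961770.5158513
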