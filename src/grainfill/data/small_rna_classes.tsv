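category	10DAF_unique	10DAF_total	15DAF_unique	15DAF_total	21DAF_unique	21DAF_total	27DAF_unique	27DAF_total	35DAF_unique	35DAF_total
Total	4478689	14248902	4770477	13297350	3930540	11378685	3884446	11647614	3518252	10658388
exon_antisense	133165	746308	133212	804510	118578	739153	123673	894862	114010	871834
exon_sense	219967	757184	228286	616801	220097	503337	218837	499487	190991	453826
intron_antisense	130900	452915	140388	346714	115639	218944	116330	198276	102339	174627
intron_sense	138967	500657	151203	435494	124176	294757	127163	282784	112208	261087
miRNA	5693	1073707	5932	1146820	4768	1114668	4985	1141378	4930	1145735
rRNA	78926	1143956	74912	1104228	88092	1653911	95275	1798049	88828	1416786
repeat	1335756	3100009	1506174	3275580	1247244	2539845	1258742	2432808	1138203	2248862
snRNA	1623	3734	1246	2260	1258	2695	1319	2734	1191	2368
snoRNA	2729	5431	2320	4368	1926	3423	2045	3535	1798	3127
tRNA	8815	270468	10435	391405	10829	573145	12300	664809	12391	474220
No_annotation	2422148	6194533	2516369	5169170	1997933	3734807	1923777	3728892	1751363	3605916
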