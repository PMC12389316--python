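gene_id	gene_length_bp	exon_count	protein_length_aa	other_domains	chromosome	clade
Aqcoe7G044700.1	6524	5	1312	0	7	1
AT3G42670	4288	5	1257	0	3	1
AT5G20420	5153	5	1262	0	5	1
Bradi1g16720.2	5594	5	1261	0	1	1
Glyma.02G261800	7254	5	1311	0	2	1
Glyma.18G023900	5085	5	1236	SAWADEE	18	1
Glyma.U027200	7454	5	1308	0	scaffold_265	1
LOC_Os07g49210.1	10,327	9	1875	Methyltransferase	7	1
Phvul.001G246400.1	4915	5	1179	0	1	1
Phvul.008G220500.1	5002	5	1311	0	8	1
Sobic.002G428700.1	5539	5	1231	0	2	1
VIT_213s0067g01950.9	5914	5	1264	0	13	1
Zm00001d022576	4684	5	1335	0	7	1
AmTr_v1.0_scaffold00142.46	3931	3	405	0	scaffold00142	2
Aqcoe2G407500.1	3357	3	761	0	2	2
Aqcoe3G096700.1	3828	3	719	0	3	2
Aqcoe3G247900.1	5106	3	1173	0	3	2
AT1G05490	4851	3	1411	0	1	2
AT3G24340	3638	3	1133	0	3	2
Bradi2g26500.6	8975	3	1507	0	2	2
Bradi2g43495.1	6754	3	1286	0	2	2
Bradi3g50300.2	6593	3	1416	0	3	2
Glyma.08G339800	4517	3	1149	0	8	2
Glyma.08G339900	7386	3	1247	0	8	2
Glyma.09G229400	3769	5	618	0	9	2
Glyma.12G006900	4114	3	1167	0	12	2
LOC_Os02g43460.1	5383	3	1440	0	2	2
LOC_Os05g32610.1	5705	3	1446	0	5	2
Phvul.008G139600.1	4598	3	1143	0	8	2
Phvul.008G139700.1	4337	3	1219	0	8	2
Sobic.004G299200.2	5147	4	1279	0	4	2
Sobic.009G126700.2	7022	3	1459	0	9	2
VIT_202s0012g00110.1	1938	1	646	0	2	2
Zm00001d038113	7648	4	1436	0	6	2
Zm00001d051324	4853	3	1338	0	4	2
AmTr_v1.0_scaffold00002.323	15,347	9	1095	0	scaffold00002	3
Aqcoe5G183800.1	8214	6	1060	0	5	3
Aqcoe5G184600.1	8072	6	1027	0	5	3
AT2G16390.1	3982	5	889	0	2	3
AT2G21450.1	2947	4	817	0	2	3
Bradi1g74070.9	5856	5	974	0	1	3
Bradi3g19890.3	7475	4	948	0	3	3
Glyma.12G236100.1	7244	6	884	0	12	3
Glyma.13G201800.1	6578	6	954	0	13	3
LOC_Os03g06920.1	7317	7	1198	0	3	3
LOC_Os06g14440.1	7192	6	952	0	6	3
LOC_Os07g25390.1	6671	5	967	0	7	3
Phvul.011G210600.2	6631	6	901	0	11	3
Phvul.011G210800.1	4894	5	872	0	11	3
Sobic.001G494100.1	6270	6	946	0	1	3
Sobic.007G034200.1	6488	6	971	0	7	3
VIT_203s0038g00030.2	13,882	5	973	0	3	3
VIT_206s0004g08480.3	8920	5	976	0	6	3
Zm00001d024677	5604	6	951	0	10	3
Zm00001d049605	7240	5	978	0	4	3
Pp3c25_10710V3.1	8807	12	1534	SAWADEE	25	outlier
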