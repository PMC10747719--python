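name	fwd	rev	motif	size_min	size_max	ta	dye	reaction	source
JS09	TTCGACCGCGTTTCCAGTTA	CCAGACTCACGGTCAGTTCC	TTC	116	131	56	FAM	M1	de_novo
JS12	TCAACATTGGCGAGGTGACA	AGGCAAGTCTACTTCTTTCCCT	TTA	128	155	55	TAMRA	M1	de_novo
ZMZ7	GAACAAATAGACCAGGCACG	TAACGACAACCGATGAAACC	TCC	215	236	56	TAMRA	M1	literature
JR03	ATACGGATCTGATGGCATGG	AGACAGCAATATCCACCCTT	GAC	235	268	57	HEX	M1	de_novo
CUJRD462	TGCTCATTTTCATCCACTATC	ACTTCCTCTCCTTCCTCTTTC	GAA	250	268	55	HEX	M2	literature
JS03	TGACGAGGTTTACCAGATGGG	CGTTCTTCTTTCAGAGTGCTGTT	GAA	90	105	58	TAMRA	M2	de_novo
JS04	CATACATATGTGGGTGGCCT	TCCTCCTCTCTCTTCCCTTT	GAA	349	367	57	TAMRA	M2	de_novo
JS07	ACCAGCAGTTCCATGTACGG	GCTCATGCCATTATCTGCTTCG	GAG	111	132	57	HEX	M2	de_novo
JS19	AGATGATTTATGGCAGCCAATGA	TGCTGGGTAAACGCATGAGT	AAG	216	252	56	FAM	M2	de_novo
JR05	GTCGCAAGCTCAGCAAATAA	TGTATGTATGGGAGGGGGAT	AAAG	194	214	57	HEX	M2	de_novo
JR07	TCTTAAGAAGAGCCAATCGC	GCTGTGTACCTCTTAGGGTT	ACCA	303	330	56	FAM	M2	de_novo
JR11	AGCTAGCTCTCAAACAACAAGC	ACAAACATGGCAACCTTCGTG	GCAGTA	140	164	53	FAM	M2	de_novo
BFU-Jr38	AGCTCCTCAAGCAAGGCTTA	GTGCATGGAACCACACTCAG	GAT	127	145	60	FAM	M3	literature
BFU-Jr277	TATTCACCCGGAGGTTTCAG	CCGAAGCCAGTCGAGTTATC	GAT	235	250	61	FAM	M3	literature
JM5446	ATGCATGCAGCTCCTACCTC	GGACGTGTCCTGGGTTTTCA	CTAG	221	249	56	HEX	M3	literature
JS05	CGGCATTACAGTCGGCAGTA	ACAATTCCCGTGCTGCATCT	GAA	93	120	57	TAMRA	M3	de_novo
JS15	ATCTCCGTGACTCCGCTCCT	ACCCGCCACCATCTTCATCTACCAA	TTG	352	377	60	TAMRA	M3	de_novo
JR02	GTTGGGCTGCCAGAGATTCT	ACGCTTCATTGGTAAACGAACG	TTC	141	168	56	HEX	M3	de_novo
JR06	TTGGAGCCCAATCAAGGATT	CACACAGAAAAGACCAGCAG	ACAG	299	319	57	HEX	M3	de_novo
JR08	ACTCCTGTCACTTGTATGCC	CCCGAGACATCAGAACCTTT	CACG	329	359	57	FAM	M3	de_novo
JR12	GCCTCTCCTCGTGCTCATTT	ACTCGCTACTTTTCAGGCCC	GAA	212	230	56	TAMRA	M3	de_novo
CUJRD102	GACAGCAGCCTTATTTTGTAAC	TTCGTCCTCTTCTTCTTCAAC	GAG	169	184	53	HEX	M4	literature
JS06	CCCTGCATGCAATCAATCACA	ATGGGACGAGTGATGGACTC	AGT	96	111	55	TAMRA	M4	de_novo
JS14	CACATCGAGTGTTTCAAGTGACA	TGCACATGAGGAATTAACTGCTT	TGC	134	149	57	FAM	M4	de_novo
JS22	AAAGTTGCTCCTCAGCTTGG	TAATTAGCAATGAACAGATGGTGG	ATC	266	293	56	FAM	M4	de_novo
JR04	TGTTCTACCATTGCTCCGAA	ACACCTAGTTAGGAGCTGGA	TCA	348	381	57	FAM	M4	de_novo
JR10	TGGGAAGGGATTTCGTGTTGT	TAAGGACGCCCATTGCCATT	TCTGA	195	215	56	TAMRA	M4	de_novo
JS02	CAACTCTGTGATTGCATGGG	GGTAACTCTCATCGCTAGGG	AAAG	383	411	57	HEX	M5	de_novo
JS13	TCTTGTCAGCATACTAAGCTTGTT	ACTAACTGCATATAGGATCAACCA	TTCT	129	158	56	HEX	M5	de_novo
JS28	AAAGGGTGAAGGAAGAAATTAGGAT	CCAAATTAAGCCAAACATGGTTGC	AAGAG	316	332	57	HEX	M5	de_novo
JR01	GAGCAGCTATGAAGAGGATGA	CTGAAATTTGTGGGGGTTCC	AGA	236	263	57	HEX	M5	de_novo
JR09	ATCACCTGATGTGGAAGCAA	CCATAGGACCCATAACGTGA	GAGGA	359	394	57	TAMRA	M5	de_novo
SSR18	GGAAAGGGATTTGAGGAGAGAT	GAAGAGGAGGAAGAAGAGGAGG	TTC	297	303	60	TAMRA	M5	literature
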