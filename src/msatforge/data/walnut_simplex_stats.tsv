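locus	population	ho	he	na	hwe_deviation
JR01	GD	0.000	0.095	2	1
JR01	LJPT	0.200	0.180	2	0
JR01	LBT	0.050	0.049	2	0
JR01	GLR	0.450	0.546	4	0
JR01	XYR	0.000	0.000	1	0
JR01	MGY	0.333	0.500	3	0
JR01	DTL	0.000	0.000	1	0
JR02	GD	0.588	0.689	5	0
JR02	LJPT	0.700	0.586	5	0
JR02	LBT	0.500	0.685	4	1
JR02	GLR	0.050	0.386	3	1
JR02	XYR	0.444	0.568	3	0
JR02	MGY	0.667	0.667	4	0
JR02	DTL	0.667	0.667	4	0
JR03	GD	0.706	0.685	5	0
JR03	LJPT	0.300	0.429	3	0
JR03	LBT	0.550	0.516	4	0
JR03	GLR	0.400	0.584	4	1
JR03	XYR	0.444	0.494	3	0
JR03	MGY	0.333	0.500	3	0
JR03	DTL	0.000	0.000	1	0
JR04	GD	0.700	0.754	6	0
JR04	LJPT	0.550	0.544	4	0
JR04	LBT	0.500	0.488	7	0
JR04	GLR	0.500	0.738	4	1
JR04	XYR	0.444	0.642	4	0
JR04	MGY	0.000	0.667	3	0
JR04	DTL	0.000	0.444	2	0
JR05	GD	0.600	0.530	5	0
JR05	LJPT	0.650	0.580	5	0
JR05	LBT	0.550	0.584	4	0
JR05	GLR	0.250	0.219	2	0
JR05	XYR	0.111	0.204	3	0
JR05	MGY	0.333	0.500	3	0
JR05	DTL	0.000	0.444	2	0
JR06	GD	0.400	0.656	4	1
JR06	LJPT	0.400	0.566	4	0
JR06	LBT	0.700	0.559	3	0
JR06	GLR	0.647	0.554	3	0
JR06	XYR	0.556	0.611	3	0
JR06	MGY	0.000	0.444	2	0
JR06	DTL	0.333	0.278	2	0
JR07	GD	0.450	0.566	4	0
JR07	LJPT	0.400	0.569	4	1
JR07	LBT	0.579	0.661	6	0
JR07	GLR	0.125	0.443	4	1
JR07	XYR	0.500	0.602	3	0
JR07	MGY	0.000	0.444	2	0
JR07	DTL	0.000	0.000	1	0
JR08	GD	0.500	0.526	3	0
JR08	LJPT	0.400	0.446	4	0
JR08	LBT	0.450	0.581	4	1
JR08	GLR	0.100	0.395	3	1
JR08	XYR	0.556	0.512	3	0
JR08	MGY	1.000	0.500	2	0
JR08	DTL	0.000	0.000	1	0
JR09	GD	0.200	0.228	4	0
JR09	LJPT	0.400	0.448	5	0
JR09	LBT	0.313	0.361	3	1
JR09	GLR	0.125	0.576	4	1
JR09	XYR	0.556	0.611	3	0
JR09	MGY	0.333	0.722	4	0
JR09	DTL	0.000	0.444	2	0
JR10	GD	0.200	0.440	5	0
JR10	LJPT	0.000	0.455	2	1
JR10	LBT	0.150	0.410	4	1
JR10	GLR	0.000	0.480	2	1
JR10	XYR	0.778	0.549	3	0
JR10	MGY	0.500	0.625	3	0
JR10	DTL	0.333	0.611	3	0
JR11	GD	0.650	0.576	3	0
JR11	LJPT	0.550	0.696	4	0
JR11	LBT	0.650	0.708	5	1
JR11	GLR	0.400	0.485	3	1
JR11	XYR	0.667	0.623	4	0
JR11	MGY	0.333	0.611	3	0
JR11	DTL	0.333	0.278	2	0
JR12	GD	0.100	0.095	2	0
JR12	LJPT	0.550	0.504	4	0
JR12	LBT	0.300	0.329	3	0
JR12	GLR	0.650	0.489	2	0
JR12	XYR	0.111	0.401	2	0
JR12	MGY	0.667	0.667	4	0
JR12	DTL	0.667	0.667	3	0
JS02	GD	0.650	0.545	4	0
JS02	LJPT	0.632	0.536	3	0
JS02	LBT	0.500	0.480	2	0
JS02	GLR	0.000	0.000	1	0
JS02	XYR	0.000	0.000	1	0
JS02	MGY	0.000	0.000	1	0
JS02	DTL	0.000	0.444	2	0
JS03	GD	0.650	0.731	5	0
JS03	LJPT	0.400	0.445	5	0
JS03	LBT	0.750	0.560	5	0
JS03	GLR	0.474	0.411	2	0
JS03	XYR	0.111	0.105	2	0
JS03	MGY	1.000	0.500	2	0
JS03	DTL	0.667	0.611	3	0
JS04	GD	0.550	0.696	5	0
JS04	LJPT	0.950	0.775	6	0
JS04	LBT	0.400	0.700	5	1
JS04	GLR	0.400	0.471	3	0
JS04	XYR	0.444	0.660	3	0
JS04	MGY	0.333	0.500	3	0
JS04	DTL	0.000	0.000	1	0
JS05	GD	0.650	0.565	3	0
JS05	LJPT	0.750	0.518	5	0
JS05	LBT	0.550	0.526	3	0
JS05	GLR	0.000	0.000	1	0
JS05	XYR	0.333	0.500	2	0
JS05	MGY	0.000	0.000	1	0
JS05	DTL	0.000	0.000	1	0
JS06	GD	0.700	0.599	3	1
JS06	LJPT	0.600	0.595	3	0
JS06	LBT	0.550	0.511	3	0
JS06	GLR	0.000	0.000	1	0
JS06	XYR	0.667	0.494	2	0
JS06	MGY	0.000	0.000	1	0
JS06	DTL	0.000	0.000	1	0
JS07	GD	0.350	0.499	2	0
JS07	LJPT	0.700	0.495	2	0
JS07	LBT	0.550	0.545	3	0
JS07	GLR	0.000	0.320	2	1
JS07	XYR	0.556	0.475	2	0
JS07	MGY	0.000	0.444	2	0
JS07	DTL	0.000	0.000	1	0
JS09	GD	0.550	0.443	4	0
JS09	LJPT	0.400	0.341	4	0
JS09	LBT	0.500	0.415	5	0
JS09	GLR	0.000	0.000	1	0
JS09	XYR	0.444	0.426	3	0
JS09	MGY	0.333	0.500	3	0
JS09	DTL	0.000	0.000	1	0
JS12	GD	0.450	0.421	3	1
JS12	LJPT	0.700	0.579	3	0
JS12	LBT	0.550	0.629	3	0
JS12	GLR	0.350	0.469	2	0
JS12	XYR	0.667	0.648	4	0
JS12	MGY	0.000	0.444	2	0
JS12	DTL	0.000	0.444	2	0
JS13	GD	0.600	0.585	3	0
JS13	LJPT	0.500	0.619	5	0
JS13	LBT	0.500	0.686	6	0
JS13	GLR	0.000	0.000	1	0
JS13	XYR	0.667	0.648	3	0
JS13	MGY	0.333	0.611	3	0
JS13	DTL	1.000	0.611	3	0
JS14	GD	0.650	0.546	4	0
JS14	LJPT	0.800	0.636	4	0
JS14	LBT	0.550	0.659	3	0
JS14	GLR	0.000	0.000	1	0
JS14	XYR	0.375	0.430	2	0
JS14	MGY	0.000	0.000	1	0
JS14	DTL	1.000	0.500	2	0
JS15	GD	0.100	0.095	2	0
JS15	LJPT	0.600	0.670	4	0
JS15	LBT	0.600	0.574	5	0
JS15	GLR	0.300	0.255	2	0
JS15	XYR	0.556	0.512	3	0
JS15	MGY	0.000	0.444	2	0
JS15	DTL	0.000	0.000	1	0
JS19	GD	0.368	0.499	4	1
JS19	LJPT	0.368	0.716	6	1
JS19	LBT	0.400	0.713	6	1
JS19	GLR	0.000	0.000	1	0
JS19	XYR	0.000	0.000	1	0
JS19	MGY	0.000	0.444	2	0
JS19	DTL	0.333	0.278	2	0
JS22	GD	0.650	0.785	6	0
JS22	LJPT	0.600	0.606	4	0
JS22	LBT	0.600	0.718	7	0
JS22	GLR	0.000	0.000	1	0
JS22	XYR	0.444	0.346	2	0
JS22	MGY	0.000	0.444	2	0
JS22	DTL	0.333	0.278	2	0
JS28	GD	0.050	0.049	2	0
JS28	LJPT	0.316	0.359	4	0
JS28	LBT	0.200	0.261	3	0
JS28	GLR	0.400	0.420	2	0
JS28	XYR	0.111	0.105	2	0
JS28	MGY	0.333	0.500	3	0
JS28	DTL	0.000	0.000	1	0
BFU-Jr277	GD	0.600	0.486	3	0
BFU-Jr277	LJPT	0.421	0.486	4	0
BFU-Jr277	LBT	0.400	0.429	3	0
BFU-Jr277	GLR	0.500	0.455	2	0
BFU-Jr277	XYR	0.222	0.346	2	0
BFU-Jr277	MGY	0.000	0.000	1	0
BFU-Jr277	DTL	0.000	0.000	1	0
BFU-Jr38	GD	0.400	0.515	3	1
BFU-Jr38	LJPT	0.700	0.696	5	0
BFU-Jr38	LBT	0.600	0.581	7	0
BFU-Jr38	GLR	0.316	0.432	2	0
BFU-Jr38	XYR	0.667	0.599	4	0
BFU-Jr38	MGY	0.000	0.000	1	0
BFU-Jr38	DTL	0.000	0.000	1	0
CUJRD102	GD	0.200	0.255	2	0
CUJRD102	LJPT	0.333	0.292	3	0
CUJRD102	LBT	0.316	0.332	2	0
CUJRD102	GLR	0.421	0.499	2	0
CUJRD102	XYR	0.222	0.198	2	0
CUJRD102	MGY	0.333	0.500	3	0
CUJRD102	DTL	0.333	0.611	3	0
CUJRD462	GD	0.100	0.185	3	0
CUJRD462	LJPT	0.550	0.661	5	0
CUJRD462	LBT	0.300	0.404	4	0
CUJRD462	GLR	0.650	0.489	2	0
CUJRD462	XYR	0.222	0.346	2	0
CUJRD462	MGY	0.333	0.611	3	0
CUJRD462	DTL	0.000	0.444	2	0
JM5446	GD	0.350	0.374	3	0
JM5446	LJPT	0.250	0.301	3	0
JM5446	LBT	0.350	0.289	2	0
JM5446	GLR	0.000	0.000	1	0
JM5446	XYR	0.111	0.105	2	0
JM5446	MGY	0.333	0.611	3	0
JM5446	DTL	0.333	0.611	3	0
SSR18	GD	0.850	0.674	8	0
SSR18	LJPT	0.700	0.596	3	0
SSR18	LBT	0.650	0.569	4	0
SSR18	GLR	0.400	0.434	3	0
SSR18	XYR	0.778	0.660	3	0
SSR18	MGY	0.667	0.500	3	0
SSR18	DTL	0.333	0.278	2	0
ZMZ7	GD	0.100	0.095	2	0
ZMZ7	LJPT	0.350	0.503	4	0
ZMZ7	LBT	0.750	0.630	6	0
ZMZ7	GLR	0.450	0.399	2	0
ZMZ7	XYR	0.222	0.346	2	0
ZMZ7	MGY	0.333	0.278	2	0
ZMZ7	DTL	0.333	0.500	3	0
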