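gene	base_mean	lfc	padj	direction
CG33282	151.6682	10.615861	1.41E-26	UP
CG43291	127.779	9.886821	1.37E-21	UP
CG14568	66.23119	9.420866	2.05E-19	UP
CG18853	400.6557	2.007146	1.24E-16	UP
CG14569	50.51375	9.029823	4.18E-15	UP
TotX	1878.838	4.171616	2.34E-13	UP
CG11453	781.4222	2.450503	2.44E-12	UP
CG14573	38.20774	8.627094	2.30E-11	UP
snRNA:U5:38ABb	20.88761	7.755002	1.31E-09	UP
ChLD3	197.9505	3.749117	2.22E-08	UP
CG14893	241.741	2.321437	2.37E-08	UP
CG5391	196.1082	3.359478	3.20E-08	UP
CG9822	18.66914	7.594104	9.72E-07	UP
lncRNA:let7C	127.7321	2.800375	1.68E-06	UP
rhi	15.18903	7.296804	5.76E-06	UP
Cpr64Ac	159.6634	3.147724	1.85E-05	UP
BomBc2	686.6249	2.040056	3.03E-05	UP
CG7365	168.1691	2.426052	3.67E-05	UP
CG7194	261.1134	4.672395	5.94E-05	UP
phr	286.2989	3.659104	1.11E-04	UP
pip	233.9657	2.687781	2.98E-04	UP
CG3823	621.9015	2.060051	3.29E-04	UP
CG11382	9.605189	6.635621	5.07E-04	UP
CG15322	111.2228	3.869597	7.06E-04	UP
reb	95.8132	2.903344	1.26E-03	UP
CG8468	65.09113	3.285487	1.46E-03	UP
CG15347	57.91432	3.72811	2.14E-03	UP
CG32301	37.79015	4.819695	2.23E-03	UP
asRNA:CR45924	10.71271	6.793449	3.17E-03	UP
CG33468	379.8354	5.093014	3.24E-03	UP
CG4017	9.313039	6.590287	3.42E-03	UP
CG10352	39.66282	3.973475	5.66E-03	UP
mas	38.57673	4.347085	5.77E-03	UP
CG3713	43.90829	4.295894	5.91E-03	UP
Acp54A1	8.659525	6.484274	9.85E-03	UP
lncRNA:CR44529	67.6608	3.983908	9.85E-03	UP
CR43377	186.1008	2.166802	1.06E-02	UP
CG11263	11.22834	6.860337	1.28E-02	UP
CG13280	7.332412	6.244676	1.31E-02	UP
Cyp4ac1	190.557	2.134352	1.34E-02	UP
CG3285	10.84957	6.810982	1.49E-02	UP
lncRNA:CR46350	49.90847	3.435516	1.95E-02	UP
lncRNA:CR43607	6.466344	6.064776	2.07E-02	UP
lncRNA:CR42646	49.74665	3.721334	2.17E-02	UP
CG40485	161.9931	2.386988	2.21E-02	UP
CG32219	6.156637	5.994021	2.39E-02	UP
CG33178	60.14983	2.632998	2.64E-02	UP
Ssk	31.34168	3.569874	2.66E-02	UP
BomS4	79.01108	2.553112	2.95E-02	UP
lncRNA:CR45625	36.27471	4.045288	3.22E-02	UP
CG30484	8.532839	6.464183	3.28E-02	UP
CG31516	45.75478	4.110221	3.47E-02	UP
CG3347	17.54727	4.648723	3.78E-02	UP
CG11318	7.982785	5.872617	4.48E-02	UP
Marf1	17.71153	4.238299	4.48E-02	UP
lncRNA:CR44895	13.28827	4.046651	4.48E-02	UP
CG32266	8.157953	6.399215	4.63E-02	UP
CG5321	51.3329	2.99039	4.94E-02	UP
Npc2h	17.61192	-22.0773	1.66E-10	DOWN
lncRNA:CR44430	28.39738	-8.372309	7.70E-09	DOWN
mthl3	482.2042	-2.22738	4.81E-04	DOWN
CR40190	517.9799	-2.691215	6.81E-04	DOWN
lncRNA:CR43963	102.2304	-2.463245	1.49E-03	DOWN
m	328.4224	-4.003528	1.55E-03	DOWN
lovit	15.53762	-7.502503	2.33E-03	DOWN
Ect3	61.70978	-2.476102	2.39E-03	DOWN
Obp56h	2454.115	-2.568066	2.60E-03	DOWN
snoRNA:Or-CD14	8.403595	-6.617001	3.42E-03	DOWN
Cyp28c1	243.3068	-2.591403	4.30E-03	DOWN
Rtnl2	23.49235	-5.517407	7.55E-03	DOWN
CG14085	167.1615	-4.552728	8.84E-03	DOWN
smp-30	761.1948	-2.021329	9.00E-03	DOWN
CR43383	60.52044	-2.476486	1.01E-02	DOWN
CCHa2	23.31323	-4.14435	1.95E-02	DOWN
GstD5	2878.605	-3.400804	2.14E-02	DOWN
CG3117	14.7746	-7.42975	2.21E-02	DOWN
CG9109	47.16456	-2.279434	2.67E-02	DOWN
CG11437	8.387962	-6.611737	3.50E-02	DOWN
CG1722	55.71163	-2.083056	3.53E-02	DOWN
CG11703	11.74775	-7.099016	3.54E-02	DOWN
lncRNA:CR43771	11.76853	-7.101085	3.63E-02	DOWN
CG18748	7.2387	-6.400137	4.80E-02	DOWN
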