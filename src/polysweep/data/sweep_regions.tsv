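region	chrom	start_cm	end_cm	pops	methods	genes
1A-216.5:217.2	1A	216.5	217.2	Post70, QLD, SA	Fst, nSL	QPh, QSe, QKps, QSpad
1A-241.9:241.9	1A	241.9	241.9	Post70	nSL	-
1A-256.1:256.1	1A	256.1	256.1	WA	XPCLR	LD with Glu-A1
1A-289.1:297.4	1A	289.1	297.4	Post70	Fst, XPCLR	-
1A-351.3:357.3	1A	351.3	357.3	Post70	Fst	-
1B-142:142.9	1B	142.0	142.9	QLD, WA	nSL	-
1B-195.4:227.2	1B	195.4	227.2	Post70, All, QLD, SA, VIC, WA	All	Glu-B1u, QSe, QAD_Yld
1B-238.3:240.6	1B	238.3	240.6	QLD, VIC	Fst, nSL	-
1B-255.1:260.8	1B	255.1	260.8	VIC	Fst, XPCLR	LD with Glu-B1c,e
1B-306.5:306.5	1B	306.5	306.5	QLD	Fst	-
1B-355.4:368.3	1B	355.4	368.3	Post70, QLD	Fst	-
1B-431.2:449.8	1B	431.2	449.8	SA	Fst, XPCLR	-
1D-108.9:120.6	1D	108.9	120.6	Post70	Fst	-
1D-263.8:264	1D	263.8	264.0	QLD, VIC, WA	iHS, nSL	QHi?
2A-158:158	2A	158.0	158.0	VIC	XPCLR	-
2A-342.7:342.7	2A	342.7	342.7	Post70, QLD	nSL	QSdw, QW, QPhys
2A-355.6:363	2A	355.6	363.0	Post70	nSL, XPCLR	QYld, TaCwi-A1?
2A-413.7:413.7	2A	413.7	413.7	SA	nSL	-
2B-84.9:87.4	2B	84.9	87.4	QLD, SA	Fst, XPCLR	QTkw
2B-216.6:221.6	2B	216.6	221.6	Post70	Fst	Ppd-B1?
2B-236.5:236.5	2B	236.5	236.5	NSW	nSL	-
2B-283.4:291.9	2B	283.4	291.9	VIC	Fst, XPCLR	QZad, QEet, QW, QEv, QFll
2B-311.4:320.4	2B	311.4	320.4	Post70, SA WA	Fst, nSL, XPCLR	Sus-2B, QTpa, QTkw, QGn; QFlw
2B-504.4:504.4	2B	504.4	504.4	QLD	XPCLR	-
2D-60.3:66.6	2D	60.3	66.6	SA, VIC	nSL	-
3A-107.2:107.2	3A	107.2	107.2	WA	XPCLR	-
3A-285.2:285.2	3A	285.2	285.2	QLD	XPCLR	-
3A-321.8:321.8	3A	321.8	321.8	Post70	Fst	-
3A-336.6:336.6	3A	336.6	336.6	WA	nSL	-
3B-56.5:56.6	3B	56.5	56.6	All comparisons	his	QHi
3B-132:132	3B	132.0	132.0	VIC	XPCLR	-
3B-239.1:250.3	3B	239.1	250.3	Post70, QLD	Fst	QYld, Q.CT-gf, QKpsm, QTkw, QNdvi
3B-259.1:293.4	3B	259.1	293.4	Post70, QLD, SA, VIC, WA	Fst, XPCLR	QAD_Yld, QAD_Gn, QSe, QDso, QDst, QBmt, QTkw, QNdvi. QYld
3B-324:324	3B	324.0	324.0	QLD	XPCLR	-
3D-240.6:240.6	3D	240.6	240.6	VIC	Fst	-
3D-283.7:286	3D	283.7	286.0	QLD	Fst, XPCLR	-
4A-589.7:589.7	4A	589.7	589.7	VIC	XPCLR	-
4B-107.3:107.3	4B	107.3	107.3	Post70	Fst	-
4B-180.5:182.5	4B	180.5	182.5	QLD, VIC	nSL	-
4D-30.5:30.5	4D	30.5	30.5	VIC	XPCLR	-
4D-159.5:159.5	4D	159.5	159.5	WA	XPCLR	-
5A-77.8:79.2	5A	77.8	79.2	Post70, All, SA, VIC, WA	nSL	Psy-A2
5A-216.7:216.8	5A	216.7	216.8	Post70	Fst	-
5A-237.4:237.4	5A	237.4	237.4	SA	nSL	-
5A-266.6:266.6	5A	266.6	266.6	QLD	nSL	-
5A-460.6:466.8	5A	460.6	466.8	Post70	Fst	LD with Vrn-A1, QYld
5A-690.4:699.7	5A	690.4	699.7	Post70	Fst	-
5B-168.3:168.3	5B	168.3	168.3	VIC	XPCLR	-
5B-222.6:222.7	5B	222.6	222.7	WA	Fst	Srp5B?
5B-290.3:290.3	5B	290.3	290.3	VIC	XPCLR	-
5B-323.8:324.8	5B	323.8	324.8	Post70	Fst	-
5B-377:379	5B	377.0	379.0	WA	Fst	QEet
5B-397.5:397.5	5B	397.5	397.5	VIC	nSL	-
5B-420.8:420.8	5B	420.8	420.8	QLD	nSL	-
5D-180:194.2	5D	180.0	194.2	Post70, SA, WA	nSL, XPCLR	-
5D-214.5:223	5D	214.5	223.0	SA, VIC	nSL	-
5D-365.2:365.2	5D	365.2	365.2	SA	nSL	-
5D-406.4:410.2	5D	406.4	410.2	SA	nSL	-
5D-503.5:513.6	5D	503.5	513.6	Post70	Fst	-
6A-32.4:32.4	6A	32.4	32.4	Post70	Fst	-
6A-103.7:105.9	6A	103.7	105.9	Post70	Fst	-
6A-145:145	6A	145.0	145.0	Post70, VIC	Fst, nSL	-
6A-188.9:205.5	6A	188.9	205.5	Post70	Fst	TaGw2-6A, CCD4, QEv, QSPADLLg, QBM, QYld, QTkw, QTwt, QKpsl, QKpsm, QFlw, QTpa, QWsc, QGpc, Q.Phys, QW
6B-164:164	6B	164.0	164.0	SA	nSL	-
6B-202:207.6	6B	202.0	207.6	Post70	Fst	-
6B-214.3:214.3	6B	214.3	214.3	SA	nSL	-
6B-226.8:237.7	6B	226.8	237.7	QLD	nSL	-
6B-255.2:272.3	6B	255.2	272.3	Post70	Fst	TaGw2-6B?
6B-377.3:377.3	6B	377.3	377.3	Post70	nSL	-
6B-388.3:398	6B	388.3	398.0	Post70	Fst, XPCLR	Cre8
7A-98.3:98.4	7A	98.3	98.4	QLD	Fst, XPCLR	-
7A-123.7:123.8	7A	123.7	123.8	SA	Fst	-
7A-371.3:399.2	7A	371.3	399.2	All comparisons	All	TaSus1-7A, TaSAP1-7A, QGn, QEet, QEv, QKpsm, QZad, QYld, QTkw, QGpc, QFcb, QW
7A-436:438.4	7A	436.0	438.4	Post70, QLD	nSL, XPCLR	-
7A-624.4:624.6	7A	624.4	624.6	VIC	Fst, XPCLR	-
7A-670.6:670.6	7A	670.6	670.6	SA	Fst	Psy-A1
7B-229.5:229.8	7B	229.5	229.8	Post70, NSW, QLD, SA, VIC, WA	iHS, nSL	QEet, QZad, QBmt, QWsc
7B-328.9:328.9	7B	328.9	328.9	VIC	XPCLR	-
7B-427.9:427.9	7B	427.9	427.9	VIC	XPCLR	-
7B-448.1:448.1	7B	448.1	448.1	QLD	nSL	-
7D-3.5:7.7	7D	3.5	7.7	Post70	Fst	-
7D-224.5:224.5	7D	224.5	224.5	Post70	XPCLR	-
7D-265.7:265.7	7D	265.7	265.7	VIC	nSL	-
7D-279.6:282.9	7D	279.6	282.9	Post70, SA	nSL	-
7D-298.9:309.4	7D	298.9	309.4	Post70, NSW, QLD, SA, WA	nSL	QFll
7D-414.5:414.5	7D	414.5	414.5	Post70	XPCLR	-
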