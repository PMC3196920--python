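sample	diagnosis	state	age	sex	efs	ovs	status	pretreated
R194	Ewing	Primary	32	F	11,7	15,6	Dead	-
R196	Ewing	Primary	5	M	14,0	20,7	Dead	-
R29	Ewing	Primary	21	M	4,6	4,6	Dead	-
R30	Ewing	Primary	26	F	28,6	48,9	NED	+
R33	Ewing	Primary	15	M	16,6	16,6	Dead	-
R34	Ewing	Primary	18	M	19,4	56,5	AWD	+
R35	Ewing	Primary	16	F	10,0	13,6	Dead	+
R37	Ewing	Primary	11	M	9,8	9,8	Dead	+
R38	Ewing	Primary	23	M	11,3	11,3	Dead	-
R39	Ewing	Primary	16	F	47,0	47,0	Dead	-
R40	Ewing	Primary	24	M	18,2	117,3	NED	-
R41	Ewing	Primary	15	M	125,1	125,1	NED	-
R42	Ewing	Primary	18	M	192,2	192,2	NED	-
R43	Ewing	Recurrence	17	F	24,8	35,7	Dead	+
R44	Ewing	Recurrence	30	F	19,8	25,6	Dead	+
R45	Askin	Recurrence	15	M	17,9	24,6	Dead	+
R46	PNET	Primary	7	F	22,1	64,2	Dead	-
R48	Ewing	Metastasis	17	M	31,6	46,2	Dead	+
R49	Ewing	Metastasis	34	M	18,6	126,2	NED	+
R50	PNET	Metastasis	16	M	58,3	99,3	Dead	-
R51	Askin	Primary	24	M	4,6	10,9	Dead	+
R52	Ewing	Recurrence	22	F	14,4	23,2	Dead	+
R53	Ewing	Primary	19	F	87,7	87,7	NED	-
R54	Ewing	Recurrence	22	M	25,9	61,5	Dead	+
R55	PNET	Metastasis	16	F	6,8	8,5	Dead	-
R57	Ewing	Primary	11	M	2,0	8,7	Dead	-
R58	Ewing	Primary	22	M	13,4	13,4	Dead	-
R60	Ewing	Primary	12	M	121,5	121,5	NED	-
R61	Ewing	Primary	15	M	16,2	16,2	NED	-
R62	Ewing	Primary	16	M	117,6	117,6	NED	-
R63	Ewing	Primary	13	M	43,4	43,4	NED	-
R64	Ewing	Primary	25	M	15,3	21,3	Dead	-
R65	Ewing	Primary	20	F	11,0	11,0	Dead	-
R67	Ewing	Primary	14	M	16,7	29,4	Dead	-
R69	Ewing	Primary	9	F	62,6	62,6	NED	-
R72	PNET	Primary	32	F	31,5	117,7	NED	-
R74	PNET	Primary	27	M	110,4	110,4	NED	-
R75	PNET	Primary	14	M	9,8	25,4	Dead	-
R78	PNET	Primary	11	F	69,5	69,5	NED	-
R79	PNET	Primary	21	M	127,1	127,1	NED	-
R80	PNET	Primary	8	F	23,9	68,5	NED	-
R81	Ewing	Metastasis	24	M	34,4	81,4	Dead	+
R83	PNET	Metastasis	4	F	70,1	129,1	NED	+
R84	Ewing	Metastasis	9	M	27,9	41,6	Dead	+
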