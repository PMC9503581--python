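# Per-(residue type, atom) Gaussian chemical-shift reference statistics.
# Compiled from public BMRB chemical-shift statistics (full database averages,
# diamagnetic proteins); means and standard deviations in ppm.
# Columns: residue(1-letter)  atom  mean_ppm  sd_ppm  count
A	N	123.2	3.5	60000
A	CA	53.1	2.0	65000
A	CB	19.0	1.8	60000
A	C	177.7	2.1	50000
R	N	120.8	3.6	35000
R	CA	56.8	2.3	38000
R	CB	30.7	1.8	35000
R	CG	27.2	1.2	25000
R	CD	43.2	0.9	25000
R	CZ	159.8	1.2	5000
R	C	176.4	2.0	30000
N	N	118.9	4.0	32000
N	CA	53.5	1.9	35000
N	CB	38.7	1.7	33000
N	CG	176.8	1.4	10000
N	C	175.2	1.8	27000
D	N	120.6	3.9	40000
D	CA	54.7	2.0	43000
D	CB	40.9	1.6	40000
D	CG	179.2	1.8	8000
D	C	176.4	1.7	33000
C	N	120.0	4.6	12000
C	CA	58.2	3.3	13000
C	CB	32.8	6.1	12000
C	C	174.9	2.0	10000
E	N	120.7	3.5	48000
E	CA	57.3	2.1	52000
E	CB	30.0	1.7	48000
E	CG	36.1	1.2	35000
E	CD	182.4	1.8	7000
E	C	176.9	2.0	40000
Q	N	119.9	3.6	28000
Q	CA	56.6	2.2	30000
Q	CB	29.2	1.8	28000
Q	CG	33.8	1.1	20000
Q	CD	179.7	1.3	6000
Q	C	176.3	2.0	24000
G	N	109.7	3.9	50000
G	CA	45.4	1.3	55000
G	C	174.0	1.8	42000
H	N	119.6	4.0	16000
H	CA	56.5	2.3	18000
H	CB	30.2	2.1	16000
H	CG	131.4	3.3	3000
H	CD2	120.0	3.4	8000
H	CE1	137.6	2.3	8000
H	C	175.2	2.0	13000
I	N	121.5	4.3	38000
I	CA	61.6	2.7	41000
I	CB	38.6	2.0	38000
I	CG1	27.7	1.8	28000
I	CG2	17.5	1.4	29000
I	CD1	13.4	1.7	28000
I	C	175.8	1.9	31000
L	N	121.9	3.9	55000
L	CA	55.6	2.1	58000
L	CB	42.3	1.9	55000
L	CG	26.8	1.1	38000
L	CD1	24.7	1.6	39000
L	CD2	24.1	1.7	37000
L	C	177.0	2.0	45000
K	N	121.0	3.8	48000
K	CA	56.9	2.2	51000
K	CB	32.8	1.8	48000
K	CG	24.9	1.1	33000
K	CD	28.9	1.1	32000
K	CE	41.9	0.8	30000
K	C	176.7	2.0	40000
M	N	120.1	3.6	14000
M	CA	56.1	2.2	15000
M	CB	32.9	2.2	14000
M	CG	32.0	1.2	10000
M	CE	17.1	1.6	8000
M	C	176.3	2.1	12000
F	N	120.5	4.2	25000
F	CA	58.1	2.6	27000
F	CB	39.9	2.1	25000
F	CG	138.4	2.0	3000
F	CD1	131.5	1.2	10000
F	CD2	131.5	1.2	8000
F	CE1	130.7	1.3	9000
F	CE2	130.7	1.3	7000
F	CZ	129.2	1.6	8000
F	C	175.5	2.0	20000
P	N	136.9	4.4	8000
P	CA	63.3	1.6	30000
P	CB	31.8	1.2	28000
P	CG	27.2	1.1	20000
P	CD	50.3	1.0	20000
P	C	176.7	1.6	23000
S	N	116.3	3.6	40000
S	CA	58.7	2.1	43000
S	CB	63.8	1.5	40000
S	C	174.6	1.8	33000
T	N	115.5	4.7	36000
T	CA	62.2	2.7	39000
T	CB	69.7	1.6	36000
T	CG2	21.5	1.1	28000
T	C	174.5	1.8	30000
W	N	121.7	4.2	8000
W	CA	57.7	2.6	9000
W	CB	30.0	2.0	8000
W	CG	110.6	1.8	2000
W	CD1	126.5	1.9	4000
W	CD2	127.5	1.3	2000
W	CE2	136.2	1.3	2000
W	CE3	120.5	1.4	3000
W	CZ2	114.3	1.1	3500
W	CZ3	121.5	1.4	3000
W	CH2	123.8	1.3	3200
W	C	176.1	2.0	6500
Y	N	120.4	4.2	22000
Y	CA	58.2	2.6	24000
Y	CB	39.3	2.2	22000
Y	CG	129.9	1.7	2500
Y	CD1	133.0	1.0	9000
Y	CD2	133.0	1.0	7000
Y	CE1	117.9	1.0	9000
Y	CE2	117.9	1.0	7000
Y	CZ	156.6	2.0	2500
Y	C	175.5	2.0	18000
V	N	121.1	4.6	42000
V	CA	62.6	2.9	45000
V	CB	32.7	1.8	42000
V	CG1	21.4	1.4	32000
V	CG2	21.3	1.6	31000
V	C	175.7	1.9	34000
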