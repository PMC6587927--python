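name	x	y
Fp1	-0.120000	0.800000
AF7	-0.627681	0.620000
AF3	-0.313841	0.620000
F1	-0.178606	0.450000
F3	-0.357211	0.450000
F5	-0.535817	0.450000
F7	-0.714423	0.450000
FT7	-0.780400	0.220000
FC5	-0.585300	0.220000
FC3	-0.390200	0.220000
FC1	-0.195100	0.220000
C1	-0.200000	0.000000
C3	-0.400000	0.000000
C5	-0.600000	0.000000
T7	-0.800000	0.000000
TP7	-0.780400	-0.220000
CP5	-0.585300	-0.220000
CP3	-0.390200	-0.220000
CP1	-0.195100	-0.220000
P1	-0.178606	-0.450000
P3	-0.357211	-0.450000
P5	-0.535817	-0.450000
P7	-0.714423	-0.450000
P9	-0.893029	-0.450000
PO7	-0.627681	-0.620000
PO3	-0.313841	-0.620000
O1	-0.120000	-0.800000
Iz	0.000000	-0.950000
Oz	0.000000	-0.800000
POz	0.000000	-0.620000
Pz	0.000000	-0.450000
CPz	0.000000	-0.220000
Fpz	0.000000	0.800000
Fp2	0.120000	0.800000
AF8	0.627681	0.620000
AF4	0.313841	0.620000
AFz	0.000000	0.620000
Fz	0.000000	0.450000
F2	0.178606	0.450000
F4	0.357211	0.450000
F6	0.535817	0.450000
F8	0.714423	0.450000
FT8	0.780400	0.220000
FC6	0.585300	0.220000
FC4	0.390200	0.220000
FC2	0.195100	0.220000
FCz	0.000000	0.220000
Cz	0.000000	0.000000
C2	0.200000	0.000000
C4	0.400000	0.000000
C6	0.600000	0.000000
T8	0.800000	0.000000
TP8	0.780400	-0.220000
CP6	0.585300	-0.220000
CP4	0.390200	-0.220000
CP2	0.195100	-0.220000
P2	0.178606	-0.450000
P4	0.357211	-0.450000
P6	0.535817	-0.450000
P8	0.714423	-0.450000
P10	0.893029	-0.450000
PO8	0.627681	-0.620000
PO4	0.313841	-0.620000
O2	0.120000	-0.800000
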