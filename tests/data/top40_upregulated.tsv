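Gene symbol	logFC	adj. P.Val
IL6	5,1	7,50E-05
CSF3	5,0	1,84E-05
C2CD4B	4,7	5,43E-05
SERPINA3	4,5	9,16E-05
RND1	4,4	4,81E-06
FAM71A	4,3	1,53E-04
CSF3	4,2	1,39E-03
EGR3	4,2	2,41E-06
IL8	4,1	2,69E-04
C2CD4B	4,1	1,02E-04
CXCL2	4,0	6,15E-06
ICAM4	4,0	1,99E-05
MAFF	4,0	1,95E-04
MAFA	4,0	2,89E-04
ADAMTS4	3,9	4,76E-04
ATF3	3,9	3,03E-04
ICAM4	3,8	2,39E-05
FOSL1	3,8	4,85E-06
ABL2	3,8	2,14E-04
ARC	3,7	6,61E-04
GEM	3,7	3,79E-04
TNFSF9	3,7	1,64E-05
AMPD3	3,7	2,16E-03
GFPT2	3,7	5,27E-06
NR4A1	3,7	6,55E-03
MOB4	3,7	2,09E-03
CCL21	3,6	1,39E-03
UBC	3,6	1,64E-03
C2CD4B	3,6	4,81E-06
EGR3	3,6	2,39E-04
SOCS3	3,6	8,86E-07
HAS1	3,6	2,37E-03
NA	3,5	4,99E-04
RGS16	3,4	6,37E-05
NR4A1	3,4	7,89E-05
DES	3,4	4,77E-04
CALCA	3,3	3,75E-03
ATF3	3,3	4,84E-04
RRAD	3,3	2,87E-06
NFKBIZ	3,3	2,59E-03
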