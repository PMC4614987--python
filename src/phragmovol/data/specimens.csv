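specimen_id,taxon,maturity,sex,max_diameter_mm,n_chambers,n_chambers_uncertain
Nm.1,Normannites mitis,mature,male,50,60,yes
Nm.2,Normannites mitis,mature,male,49,59,yes
7,Nautilus pompilius,mature,female,189,35,no
8,Nautilus pompilius,mature,female,152,30,no
10,Nautilus pompilius,mature,female,175,32,no
11,Nautilus pompilius,mature,female,165,30,no
12,Nautilus pompilius,mature,female,168,33,no
15,Nautilus pompilius,mature,female,189,33,no
16,Nautilus pompilius,mature,male,183,33,no
17,Nautilus pompilius,mature,male,183,33,no
20,Nautilus pompilius,immature,indeterminate,105,26,no
23,Nautilus pompilius,immature,indeterminate,112,26,no
30,Nautilus pompilius,immature,indeterminate,147,30,no
31,Nautilus pompilius,immature,indeterminate,136,29,no
32,Nautilus pompilius,immature,indeterminate,136,32,no
33,Nautilus pompilius,immature,indeterminate,135,27,no
34,Nautilus pompilius,immature,indeterminate,144,32,no
35,Nautilus pompilius,immature,indeterminate,124,28,no
36,Nautilus pompilius,immature,indeterminate,157,37,no
38,Nautilus pompilius,mature,male,150,31,no
39,Nautilus pompilius,mature,male,147,32,no
40,Nautilus pompilius,mature,male,151,30,no
41,Nautilus pompilius,mature,male,184,34,no
42,Nautilus pompilius,mature,female,169,33,no
43,Nautilus pompilius,mature,male,155,31,no
44,Nautilus pompilius,mature,male,164,35,no
46,Nautilus pompilius,mature,male,160,31,no
48,Nautilus pompilius,mature,male,165,35,no
51,Nautilus pompilius,mature,female,179,33,no
53,Nautilus pompilius,mature,male,181,36,no
54,Nautilus pompilius,mature,male,164,29,no
56,Nautilus pompilius,mature,female,176,32,no
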