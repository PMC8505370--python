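guild	component	weight
BF1	enrichment	3.2
BF2	basal	0.8
BF3	structure	1.8
BF4	structure	3.2
BF5	structure	5.0
FF1	excluded	0
FF2	enrichment	0.8
FF2	basal	0.8
FF3	structure	1.8
FF4	structure	3.2
FF5	structure	5.0
Om1	excluded	0
Om2	excluded	0
Om3	structure	1.8
Om4	structure	3.2
Om5	structure	5.0
Pr1	excluded	0
Pr2	structure	0.8
Pr3	structure	1.8
Pr4	structure	3.2
Pr5	structure	5.0
PF1	excluded	0
PF2	excluded	0
PF3	excluded	0
PF4	excluded	0
PF5	excluded	0
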