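category	k	group	count
very_slow	0	low	17
very_slow	1	low	7
very_slow	2	low	6
very_slow	3	low	4
very_slow	4	low	0
very_slow	5	low	0
very_slow	0	medium	104
very_slow	1	medium	15
very_slow	2	medium	12
very_slow	3	medium	9
very_slow	4	medium	1
very_slow	5	medium	0
very_slow	0	high	15
very_slow	1	high	2
very_slow	2	high	1
very_slow	3	high	0
very_slow	4	high	0
very_slow	5	high	0
slow	0	low	8
slow	1	low	8
slow	2	low	8
slow	3	low	6
slow	4	low	4
slow	5	low	0
slow	0	medium	31
slow	1	medium	37
slow	2	medium	25
slow	3	medium	28
slow	4	medium	18
slow	5	medium	2
slow	0	high	6
slow	1	high	4
slow	2	high	5
slow	3	high	3
slow	4	high	0
slow	5	high	0
normal	0	low	1
normal	1	low	11
normal	2	low	7
normal	3	low	7
normal	4	low	6
normal	5	low	2
normal	0	medium	2
normal	1	medium	30
normal	2	medium	42
normal	3	medium	21
normal	4	medium	26
normal	5	medium	20
normal	0	high	0
normal	1	high	1
normal	2	high	4
normal	3	high	4
normal	4	high	4
normal	5	high	5
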