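	walking	go-upstairs	go-downstairs	sitting	standing	lying
walking	0	629	597	0	0	0
go-upstairs	0	822	251	0	0	0
go-downstairs	0	137	849	0	0	0
sitting	0	1	0	0	1236	49
standing	0	0	0	0	1374	0
lying	0	10	0	0	164	1233
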