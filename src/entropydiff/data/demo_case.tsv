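feature	case1	case2	case3	case4
g01	4	4	4	4
g02	1	3	5	7
g03	2	4	6	8
g04	1	1	1	9
g05	5	5	5	5
g06	1	2	4	8
g07	10	12	14	16
g08	2	2	8	8
g09	1	10	100	1000
g10	3	6	9	12
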