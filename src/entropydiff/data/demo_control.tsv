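feature	ctrl1	ctrl2	ctrl3	ctrl4
g01	1	3	4	8
g02	1	3	5	7
g03	20	40	60	80
g04	3	3	3	3
g05	5	5	5	5
g06	8	4	2	1
g07	1	50	1	50
g08	4	4	4	4
g09	1	1	1	1000
g10	2	2	2	2
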