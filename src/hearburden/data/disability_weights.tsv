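# hearburden-weights v1
state	severity	ringing	db_low	db_high	weight	lower	upper
normal	normal	0	0	20	0	0	0
mild	mild	0	20	35	0.010	0.004	0.019
mild_ringing	mild	1	20	35	0.021	0.012	0.036
moderate	moderate	0	35	50	0.027	0.015	0.042
moderate_ringing	moderate	1	35	50	0.074	0.048	0.107
moderately_severe	moderately_severe	0	50	65	0.092	0.064	0.129
moderately_severe_ringing	moderately_severe	1	50	65	0.167	0.114	0.231
severe	severe	0	65	80	0.158	0.104	0.227
severe_ringing	severe	1	65	80	0.261	0.174	0.361
profound	profound	0	80	95	0.204	0.134	0.288
profound_ringing	profound	1	80	95	0.277	0.182	0.388
complete	complete	0	95	inf	0.215	0.143	0.307
complete_ringing	complete	1	95	inf	0.316	0.211	0.436
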