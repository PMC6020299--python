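family_id	representative_id	full_length_aa	ir_min_len	ir_window
IS5	IS5_rep	330	10	100
IS982	IS982_rep	290	10	100
IS256	IS256_rep	400	10	100
ISL3	ISL3_rep	440	10	100
Tn3	Tn3_rep	520	10	100
IS200_IS605	IS200_IS605_rep	150	10	100
IS66	IS66_rep	500	10	100
IS6	IS6_rep	230	10	100
ISAs1	ISAs1_rep	370	10	100
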