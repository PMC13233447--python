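characteristic	level	low_n	high_n
age	< 60	104	75
age	>= 60	169	197
stage	I	171	169
stage	II	24	28
stage	III	61	63
stage	IV	17	12
grade	G1/2	145	86
grade	G3	128	186
race	White	204	169
race	Others	56	84
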