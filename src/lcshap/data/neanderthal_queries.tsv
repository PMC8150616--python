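name	source	c.-67	c.21+115	c.21+235	c.125
Chagyrskaya	H. neanderthalensis	T	C	T	A
Altai	H. neanderthalensis	T	C	T	A
Vindija	H. neanderthalensis	T	C	Y	A
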