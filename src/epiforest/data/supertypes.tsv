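allele	supertype
A01:01	A1
A26:01	A1
A02:01	A2
A03:01	A3
A11:01	A3
A23:01	A24
A24:02	A24
B07:02	B7
B35:01	B7
B51:01	B7
B08:01	B8
B27:05	B27
B37:01	B44
B40:01	B44
B44:02	B44
B58:01	B58
B15:01	B62
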