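subunit	substitution	interface	ddg_kcal_mol
PsaB	M640T	B:A	-6.15
PsbF	S26F	F:E	-2.7
PsaI	S25F	I:L	-1.67
PsbE	D68N	D:E:U	-1.53
PsaC	H71P	C:B	-1
PsbE	S72P	E:D	-0.66
PsbL	N10S	B:L:M	-0.57
PsaJ	I4L	J:F	-0.54
PsaB	N636T	B:A	-0.53
PsbB	C124T	B:H	-0.53
PsbL	S10N	B:L:M	0.57
PsbD	I18T	D:X	0.66
PsbE	P72S	E:D	0.66
PsbA	L36V	A:I	0.95
PsbT	K28T	A:T:D	1.36
PsbA	E235A	A:D	1.43
PsbA	E231Q	A:B	2.43
PsbB	A471S	B:D	4
PsaC	H71N	C:B	4.23
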