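# Relative-seriality NTCP parameters. d50 in Gy (EQD2), alpha/beta in Gy.
structure	d50	gamma	alpha_beta	seriality
bladder	80	2.59	3.0	1.30
rectum	80	1.79	3.0	0.75
sigmoid_colon	80	2.20	3.0	0.70
small_bowel	60	2.10	3.0	0.14
penile_bulb	70	2.50	3.0	0.70
femoral_heads	65	2.70	3.0	1.00
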