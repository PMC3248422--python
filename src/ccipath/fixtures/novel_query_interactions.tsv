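# STITCH interaction neighborhoods of two query compounds whose pathway
# classes are unknown: N-acetylgalactosamine 4-sulfate (C16265, 14 annotated
# partners) and cyclopropylamine (C14150, 23 annotated partners).
chemical_a	chemical_b	score
C16265	C00059	0.956
C16265	C00333	0.931
C16265	C15923	0.904
C16265	C01508	0.9
C16265	C01721	0.899
C16265	C01330	0.899
C16265	C00116	0.899
C16265	C00009	0.899
C16265	C00053	0.47
C16265	C02591	0.312
C16265	C01170	0.27
C16265	C03506	0.256
C16265	C01132	0.235
C16265	C00096	0.183
C14150	C06554	0.918
C14150	C00014	0.907
C14150	C14149	0.899
C14150	C14148	0.899
C14150	C00001	0.899
C14150	C00969	0.378
C14150	C06547	0.347
C14150	C01234	0.29
C14150	C00218	0.29
C14150	C16267	0.286
C14150	C16318	0.273
C14150	C11512	0.273
C14150	C05593	0.267
C14150	C00261	0.238
C14150	C01054	0.236
C14150	C01013	0.224
C14150	C01471	0.208
C14150	C01746	0.205
C14150	C00571	0.205
C14150	C00144	0.205
C14150	C00903	0.171
C14150	C07113	0.168
C14150	C01724	0.152
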