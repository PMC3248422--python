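# STITCH interaction neighborhood of dihydrouracil (KEGG C00429):
# 32 partners with annotated metabolic pathway classes, unit-scale scores.
chemical_a	chemical_b	score
C00429	C00106	0.981
C00429	C02642	0.945
C00429	C00006	0.921
C00429	C00005	0.902
C00429	C00001	0.899
C00429	C00013	0.899
C00429	C00119	0.899
C00429	C00906	0.855
C00429	C00178	0.814
C00429	C07649	0.744
C00429	C00099	0.650
C00429	C00380	0.551
C00429	C00262	0.436
C00429	C00299	0.433
C00429	C00295	0.386
C00429	C05145	0.362
C00429	C02067	0.353
C00429	C00881	0.350
C00429	C00147	0.308
C00429	C05100	0.286
C00429	C03056	0.274
C00429	C02565	0.272
C00429	C00337	0.262
C00429	C00757	0.252
C00429	C00222	0.218
C00429	C12650	0.214
C00429	C12673	0.210
C00429	C00522	0.207
C00429	C00864	0.205
C00429	C11736	0.199
C00429	C00366	0.167
C00429	C00219	0.154
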