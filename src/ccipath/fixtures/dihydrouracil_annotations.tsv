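# KEGG pathway-class annotations for dihydrouracil (C00429) and its 32
# interaction partners; third column (truncated compound name) is metadata
# the reader ignores.
compound	class_codes	name
C00429	4,6,8	Dihydrouracil
C00106	4,6,8	Uracil
C02642	4,6,8	N-carbamoyl-be.
C00006	2,6,8	NADP
C00005	2,6	NADP(H)
C00001	2,8	Hydroxyl radic.
C00013	2	Pyrophosphate
C00119	1,4,5	Phosphoribosyl.
C00906	4	Dihydrothymine
C00178	4	Thymine
C07649	11	5-fluorouracil
C00099	1,4,6,8	Beta-alanine
C00380	4	Cytosine
C00262	4	Hypoxanthine
C00299	4	Uridine
C00295	4	Orotic acid
C05145	4	Beta-aminoisob.
C02067	4	Pseudouridine
C00881	4	Deoxycytidine
C00147	4,9	Adenine
C05100	4	Beta-ureidoiso.
C03056	8	2,6-dihydroxyp.
C02565	5	N-methylhydant.
C00337	4	Dihydroorotate
C00757	10	Berberine
C00222	1,11,6	Malonate semia.
C12650	11	Capecitabine
C12673	11	Tegafur
C00522	8	Pantoate
C00864	6,8	Pantothenic ac.
C11736	11	FUdR
C00366	4	Uric acid
C00219	3	Arachidonic ac.
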