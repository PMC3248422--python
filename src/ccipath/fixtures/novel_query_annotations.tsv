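# KEGG pathway-class annotations for the interaction partners of the two
# novel-compound queries (the queries C16265 and C14150 themselves carry no
# annotation); third column (truncated name) is ignored metadata.
compound	class_codes	name
C00059	2,4,5	sulfate
C00333	1	glucuronic acid
C15923	1	galactose
C01508	1	xylose
C01721	1	fucose
C01330	2	Na(+)
C00116	1,3	glycerol
C00009	2,7	phosphate
C00053	2,4,7	3'-phospho.pho.
C02591	1	sugar-1-phosph.
C01170	1	UDP-GlcNAc
C03506	10,5	indole-3-glyce.
C01132	1	N-acetyl-D-glucosamine
C00096	1,7	GDP-mannose
C06554	11	cyanuric acid
C00014	2,4,5,6	ammonia
C14149	11	N-cyclopropylammelide
C14148	11	c0761
C00001	2,8	hydroxyl radicals
C00969	3	reuterin
C06547	11,5	polyethylene
C01234	1,5	1-aminocyclopropane-1-carboxylic acid
C00218	2	methylamine
C16267	11	cyclopropanecarboxylic acid
C16318	3	methyl jasmonate
C11512	3	methyl jasmonate
C05593	11,5	3-hydroxyphenylacetic acid
C00261	11	benzaldehyde
C01054	3	2,3-oxidosqualene
C01013	1,6	3-hydroxypropionate
C01471	11	acrolein
C01746	10	calcium channel blocker
C00571	11	cyclohexylamine
C00144	4	guanosine monophosphate
C00903	10	cinnamaldehyde
C07113	11	acetophenone
C01724	3	lanosterol
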