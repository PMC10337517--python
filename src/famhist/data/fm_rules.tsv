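term	category	side	degree
mother	Mother	NA	1
mom	Mother	NA	1
father	Father	NA	1
dad	Father	NA	1
parent	Parent	NA	1
sister	Sister	NA	1
brother	Brother	NA	1
sibling	Sibling	NA	1
son	Son	NA	1
daughter	Daughter	NA	1
child	Child	NA	1
children	Child	NA	1
grandmother	Grandmother	NA	2
grandma	Grandmother	NA	2
grandfather	Grandfather	NA	2
grandpa	Grandfather	NA	2
grandparent	Grandparent	NA	2
aunt	Aunt	NA	2
uncle	Uncle	NA	2
cousin	Cousin	NA	3
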