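# CRP-FFL census: one row per FFL instance, printed list order preserved
type	gene
Coh1	araF
Coh1	araG
Coh1	dctA
Coh1	fecA
Coh1	fecB
Coh1	fecC
Coh1	fecD
Coh1	fecE
Coh1	fucA
Coh1	fucI
Coh1	fucK
Coh1	fucO
Coh1	fucP
Coh1	fucR
Coh1	fumC
Coh1	hyfH
Coh1	idnD
Coh1	idnK
Coh1	idnO
Coh1	lamB
Coh1	malE
Coh1	malF
Coh1	malG
Coh1	malK
Coh1	malM
Coh1	malS
Coh1	marB
Coh1	ompF
Coh1	prpB
Coh1	prpC
Coh1	prpD
Coh1	prpE
Coh1	rhaR
Coh1	sdhA
Coh1	sdhB
Coh1	sdhC
Coh1	sdhD
Coh1	srlA
Coh1	srlB
Coh1	srlD
Coh1	srlE
Coh1	sucA
Coh1	sucB
Coh1	sucC
Coh1	sucD
Coh1	xylA
Coh1	xylF
Coh1	xylG
Coh1	xylH
Coh2	gadA
Coh2	gadB
Coh2	gadB
Coh2	gadC
Coh2	gadC
Coh2	gadE
Coh2	gadE
Coh2	gadX
Coh2	gltD
Coh2	gltF
Coh2	mdtE
Coh2	mdtE
Coh2	mdtF
Coh2	mdtF
Coh2	proP
Coh3	gltD
Coh3	gltF
Coh4	acs
Coh4	actP
Coh4	aldB
Coh4	fadL
Coh4	flhC
Coh4	flhD
Coh4	glcC
Coh4	guaA
Coh4	guaB
Coh4	hlyE
Coh4	hupB
Coh4	mglA
Coh4	mglC
Coh4	mtlA
Coh4	mtlD
Coh4	mtlR
Coh4	nanA
Coh4	nanE
Coh4	nanK
Coh4	nanT
Coh4	nmpC
Coh4	xylF
Coh4	xylG
Coh4	xylH
Coh4	yiaK
Coh4	yjcH
InCoh1	cdd
InCoh1	chbB
InCoh1	cirA
InCoh1	cyoD
InCoh1	cyoD
InCoh1	cyoE
InCoh1	cyoE
InCoh1	cytR
InCoh1	entD
InCoh1	entH
InCoh1	fecA
InCoh1	fecB
InCoh1	fecC
InCoh1	fecD
InCoh1	fecE
InCoh1	fepA
InCoh1	fiu
InCoh1	flhC
InCoh1	flhD
InCoh1	fumC
InCoh1	galK
InCoh1	galK
InCoh1	galP
InCoh1	galP
InCoh1	galS
InCoh1	glcC
InCoh1	glpD
InCoh1	glpF
InCoh1	glpK
InCoh1	glpT
InCoh1	gntK
InCoh1	gntP
InCoh1	gntP
InCoh1	gntU
InCoh1	grcA
InCoh1	grcA
InCoh1	lsrA
InCoh1	lsrB
InCoh1	lsrC
InCoh1	lsrD
InCoh1	lsrF
InCoh1	lsrG
InCoh1	lsrK
InCoh1	lsrR
InCoh1	malI
InCoh1	malX
InCoh1	manX
InCoh1	manY
InCoh1	manZ
InCoh1	marB
InCoh1	mglA
InCoh1	mglA
InCoh1	mglA
InCoh1	mglB
InCoh1	mglB
InCoh1	mglB
InCoh1	mglC
InCoh1	mglC
InCoh1	mglC
InCoh1	mtlA
InCoh1	mtlD
InCoh1	mtlR
InCoh1	nagB
InCoh1	nagE
InCoh1	nupC
InCoh1	nupG
InCoh1	prpR
InCoh1	rbsA
InCoh1	rbsB
InCoh1	rbsC
InCoh1	rbsD
InCoh1	rbsK
InCoh1	rbsR
InCoh1	srlA
InCoh1	srlB
InCoh1	srlD
InCoh1	srlE
InCoh1	tsx
InCoh1	udp
InCoh1	uidA
InCoh1	uidB
InCoh1	uidC
InCoh1	uxuA
InCoh1	uxuA
InCoh1	uxuB
InCoh1	uxuB
InCoh1	xylA
InCoh2	bhsA
InCoh2	gadA
InCoh2	gadB
InCoh2	gadC
InCoh2	gadX
InCoh2	nirB
InCoh2	osmY
InCoh2	yiaJ
InCoh3	araJ
InCoh4	csgD
InCoh4	csgE
InCoh4	csgF
InCoh4	csgG
InCoh4	cyoD
InCoh4	cyoE
InCoh4	exuT
InCoh4	glpB
InCoh4	grcA
InCoh4	malE
InCoh4	malF
InCoh4	malG
InCoh4	marB
InCoh4	nrdB
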