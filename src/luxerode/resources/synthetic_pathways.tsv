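pathway_id	enzymes
histidine	hisG,hisE,hisI,hisA,hisH,hisF,hisB,hisC,hisD
tryptophan	trpE,trpG,trpD,trpC,trpA,trpB
lysine	dapA,dapB,dapD,dapC,dapE,dapF,lysA
methionine	metA,metB,metC,metE
threonine	thrA,thrB,thrC
isoleucine	ilvA,ilvB,ilvC,ilvD,ilvE
arginine	argA,argB,argC,argD,argE,argF,argG,argH
proline	proA,proB,proC
serine	serA,serB,serC
cysteine	cysE,cysK
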