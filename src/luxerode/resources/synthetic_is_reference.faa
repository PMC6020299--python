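>IS5_rep synthetic representative
MISTNNPPFKSIEIRDKPYCAMEKLNAGFKKSGATGEAKGRNIQSGLPRAITSMPVLRQLDGVENGVRSM
DPPLKNQFFARTFLSSSIDDKNQWVVDEDKPPRRNSPGGFGVLAANPKVVPLALIVNYFSLARHAAGAAR
KLGEKSAAEKLLNRVIPQDAARVYLEVIPIFKKSKETAQGVLGAENGRKDRDGPELQRNYIIAKLTQPLA
VDDGMSFKSTLPVPGNGFCLGTPDLFVVILLVVFGTMKMPGWANEEKFSKKFRQLPNEMYLKLSNTPMET
RDLLPGPEHIVSLLPVLEVVNAMTLKTMAVGTETRKMNDSEQAFGAGQLT
>IS982_rep synthetic representative
MAPCMAQSVKNQSFVTALVKFRGDVDDTALYRISAAKLSRELLQRIDVVGMQGVHAGQLKVEDQAGAIEI
VASFRSGAKLCAATAAPPASKIGFAAGPQESDVKAFLIFCKDVVEPSEQMIVEVSEEPNDGVQKFRDRGL
DDYNDPVYNIKSNEYGPARAPQWKNADEMIHQLEVYYQEHAILSMAEGVGVVDKDNRTPFDKPTNPTIFP
DTTVYSECDLLANMLGQLRLRPGDTDVFEVSRFALHARGSDTIFIVRNPKGAKKEQQFLKLITVKEAGNT
VGTAVHKGIW
>IS256_rep synthetic representative
MHGCKPVYLIRAWGVSFPISSNQRVVKNQGEVKGLLFLNSQELSTVVSDQLVLEDSRLGLERGPNRRMAG
KARYISVYLGFMTSTGKGLLDIMDDIIVCNSDRGFIERSKDTADHYDEYFTRVPPPIFRPGIVVVTDDER
VPFGMPDPAAEEFVGTLETKAYSRLPSLSQEDLREVTRDIAAGMIRLGGATTHITESKRLATHATSFCVE
GAFKGVATQNFLLYRIVIECPYATNFLHVMYGVNWAYFSTPGTEAIAALAFFSTTMWAACPRDMDLVVIT
YGDETNDMGKSGKRREAEARIERAADIALATGNRHPGRLQFGSISSQLHIAYPDVPGLDPYSPPSLSVYH
FVGKGWHFLFGFEKAATIHSTPERLGKNRRAKLKIESNRRVKCEKVGKTN
>ISL3_rep synthetic representative
MIIVLSFRTPKTKGFLIQWKEKHYPFLKTGQLSVVEQGVRVRVWSKKYAGDARLSLIAGSGVKAVKRTTS
KKWLFAGVALNRAANDTERFFSESGVIDRLSDDNKGNHQGMKKQVEGTQPGPDVALPQELAREQLSRWIV
TLAHAHAFPRMYVDLIMEDELLPIAGAESVGNTMAEILQGSVKERVHAIDKDMPNAQQALEDSLKNSQTV
TARLGAVGDHYEMLLLKIAIWLPRWSAVVAYEGRVWIQSDRMDLGDREYKQTSSKILSVYPNRGFEYKKK
IPVVQDKVENERLTAFRGAWTRIGSLKTNTREIGNGTTLSSSGLTNMAFLFLDQDKLRNPLNVMYEENDA
IRRSMFAALRVDAAKTLTDRFNVRLFVRLDDRHDFEASAVEKELNKHEKEFKHIGASAHSVDVQAAGVLD
VMQFLAAAATCGGTERNGEP
>Tn3_rep synthetic representative
MDNSTRLRYQGEGPAPPTYISVYDDIEERVEYAILAVDSQPSFVPHFSKMVVPIAGQGKLIFKASHLYGG
VRQAWAQVDVQSKPQPEADKTSRDIMGLLQRLPIDGRLTVNLELMAWPKLQRSRHGTHFSASSRGQRMNF
PVHVGRTERRQDVIGMRPLQRDGPHGKMFLYKLHYAMDTPSAAGSADGLALGKAQIGLETHEKVYSVGCD
RTPWGPLQRLDMARGVATPATYLDGDASINVCVDSVADTMVSYAKARYFKQAFWVMAHISPPGTKALRQR
IEKLCEYSPKNLGYSHDFDSNVLDKPDREVVAFVVVQGEPIVCRREEHIIADEVQKLHGAYFMDADQAIK
EGKAHDDKSKLDEVVISEGIELKDFRTGPSHDARLVVGRLENDSTVSIPRSQLLEIYINLFIENVRSMEE
TYAKFLYPTDLNNTYSFLAQANFGPGGLTDPVVLCAAAEVQELQLIIALSDKIQAHALRSGPKRTPLAAA
PFWQFIQPLQKESLITAVMLTRPGSVRSLG
>IS200_IS605_rep synthetic representative
MATAFAHCVYLQEAANSRPLNNLEHEHHVSFVVSVIGVTVDLALNEESIDEGENRNFSFGRLDRAVAPYE
KDGQADEERKAENDQTIFMVEQPEVMREKLCNAELIFRKTTFLFPNGNLIRIIENLDHPESYDLYDYTLA
WDSMLNVALG
>IS66_rep synthetic representative
MHMAGYPESIPLRAQREHGIFSRIYKQTFFLRGNDSKTEGENISPFYKISGEVAIPGLVTTRWVVTLASK
AKEFDSGGYNNLHLLAEGYQHTVPAESIRGVSTLSTQVVLGTLLRLLPLGAEFLAHLHSRRIVIGNHVYD
RASESAENKTDVSYLILSLKRRLLLGAEVANKSLEADVEANIAGMLSIKELHLLKTTYSAMRPIRTTRSS
SGLVPWDVQKDATRATNAQAMFESDAKGQLGAIEDVNGIKVSSQTNFSIPQSGRRQHFLIGGVRRAWSLA
LLAEAFPHFSDPGESRWSVIASRIAIKMDLLLVSLHRLDIRAFGQSYGAKPRGYAKAVSTFTEIALDEGK
FFASIMMEVDNLIFLTTSTELQQVPVLDPFWSPHGAPAKNLDLTTSPVDQVTRDDLTTVIFIEEAKFKYE
FPISLGKELGLEEFRNSLWELESAQNANILRFVAKELSVLVQVVSAFQNTSSKMHEMGTLRARLPTQFTT
PPVPFLADSP
>IS6_rep synthetic representative
MPEAHNCAEKGDFYHGVHRNYFSEQHEQEKPPVAALFDRLESVAVLNAHRYNGLDTDVGENFESKWSASA
TVWFRQSFEVRHGDLCRLEREIRILTIFVAIFCVACKGFERSEAIIDGSQPDAVFVKEETASREGVMLRR
PINMKMIMPFNAQACEIHTQPFQVTNKPRALFHNPSEDQAMSTALREQIDAQRILQNETISTDKRGSTTK
QATTPEYMEEHLSYIVNAMN
>ISAs1_rep synthetic representative
MRMANTMHNEQAISSIALAERAITTTDVLAHGKKDEDYILEGVWGVKFKKISSFSTSVLTGIYRTALGLK
NAPRKSMKGSRRPMAGKFLGEPLDIGMNRVLSMELAFELRSMAHDRLNWPQPNIYQAAGSEGTNQLYNII
GTQNVLSLIESSTPFPFKMTQLKRDDDEKVGIKQAQQRHIYKLVMDKVLQVSFANKAEGILDEKAVILID
VLPSEVNEVEVEEIVRAIRNFWKEQRHIQTTTAHTGQNFEKRNLAETVVPTKTKHNKYVQQDRDATLPPF
KIVTEGGSLELAALRIGLNTDAVSDGYIDSHMRRQVEFTGGTGLLNVVPDYINFALLMKVSEVNSVRQAA
YVVIVRPRGVRGEGFRRYYS
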