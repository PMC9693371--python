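>rep01
EWTEEEDKLVQEAVEKYGPNNWKAIANYLPGQSNNEIKNYFWNTKVRRKLER
>rep02
QWTQEEDQLLKETVQQYGPHNWRSISSYLPARTNSELKNHWWDSQLKKKLQR
>rep03
QWTEQEEKLLREAVEKYGAHNWRSIATQLSGRSDSEIKNYWWNARLKRKLER
>rep04
QWTEEDEKLLRQALEKFASHNWRAISSQLSGRTENELKNFWWSTRMQRRVER
>rep05
DWTEEDDKLVREALEKYGPHNWRTIASYLAARADSELKSHWWSARLQRKLQQ
>rep06
EWTDEQDRLVRESVEKYGPHNWRAISTHLPARTDSQMKNYFWDTRLKQKLEQ
>rep07
DWSDEEEQLLQQAVEQYGSHHWRAMTNHLAGRTENEIRSYFWNSRMKRQLEQ
>rep08
EWSEQEEKLLQQTVEKYSPHDWRAVAANLAGRTDNEIKNYWWNTRIKRQLER
>rep09
EWTQEEDKLLKESVEKYSPHDWRSIASHLPGQSDDEVKHYWWNTRLKRKLER
>rep10
DFTEEDDKIMREGVDQYGPNNWRAMASHIPARSEDEMRDHWWNTRLRRKLER
>rep11
DWTDEEEKMLRDAVEQYGPYNWRALGSYMPGRTDNEIKNYFWSTRLRQQLEQ
>rep12
EWTDDDDQLLREAVEKYAPHDFRSVSSHLPAKTDNEIKDFFWNARLQRKLER
>rep13
DWAEEQDKLMQDSIEKYAAHDWRTISSHLPSKTDSEIKNYWWNTRMQRKLEK
>rep14
DWAEEEERMVQEAVQQFSPQNWRAVSNHLPARTDSDIKDYWWHSRLQRKLEK
>rep15
EWTEEENKILRESVEKYAPHHWRAIAAHLPARTNNEIRNYWWHTRLKRQLQR
>rep16
DWTQEEDKIVREGAQKYSPHNWRAISSHVPGRTDDEVKNYWWNARVQRKLEQ
>rep17
EWTEDEDKLLQETVEKYGPQDWRSLAAHLPGRTDNQIKNFFWNARLQRKVQQ
>rep18
EWTEQEDKLLKEGIEKHGSHHWKSIASHLPGRTDNEIKNHFWNTRLKRRLDR
>rep19
EWTEEEEKMLRETVDKYGAHDWKSIASYIPGRTDNQVQNHFWNTRLKRQVER
>rep20
EWTEEDNKLMRDAIQKYGPHSWRAIASQMPSRSNSEIKNYFWNTRLKRKLER
>rep21
DWADEEEKILREAVEKHGAHNWRTIAAQMAGRTDNDIKSHWWNTRLKRKLER
>rep22
DWTEQEEKLVKEAVEKYAPHNWKSIGNHLPGRTDHEIKNYWWHTQLRQKLQR
>rep23
DWTEQEDKMLREAVQKYGPNDWRAIASHLPGRTDNDIKNHWWNTKLQRKLER
>rep24
DFAQEQDKVLREAVEKHGPNNWRAVANHVPGRTDNQLRNYWWNTRLRRKIER
>rep25
EWTEDEDKLLRQGVEKYGSHNWRAIASHLPGRTNNEIKNYWWNTQVRRKLEK
>rep26
EWAEDEDRMVQDAIEKHAAHNWKAMSANLPGRTDSEIQNHWWSTRLKRRMEQ
>rep27
EWTDDEDRMLRDAVERHGAHNFRAIANHLSGKTEHEIQNYWWDTRIKRKLER
>rep28
EWTQEEDQLMREALQKYGPHNWKAIANNLPGRTDDEIRNYWWDARLQKKVER
>rep29
DWTEEEDRMMKETAEKYGPHNWQAITSNLPGRTDSDMKNYWWNTRLQQRIER
>rep30
EWTEQEDKLLQEAVDKHSPHNWRGLASHVPGKTDNEIRNYWWNTRMKRRLEK
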