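>C1_anchor1
EWTEEEDKLLREAVEKYGPHNWRAIASHLPPRTDNERKNYWWNTRLKRKLCREWTEEEKKLNREAVEKYG
PHNWRAYASCLPSRTDNEIKNYWWNLYLKRKLER
>C1_anchor2
EWTEEEDKLLREAVEKYGPHNWRAMASHLPPRTDNERKNYWWNTRLKRKLEREWFEEEKKLNREAVEKYG
PHNWRAYASCLPSRTDNEIKNYWWNTYLKRKLER
>C2_anchor1
EITVEEDKLLREAVEKYGPHNWRVIAHHLPGRTDNEIKNYWWNTRLKRKLEREWTEENDKRLRDAVFKYG
PHNWRAIASHLPGRTDNEIKNYWWNTRLQRKLER
>C2_anchor2
DITVEEDKLLREAVEKYGPHNWRAIAHHLPGRTDNEIKNYWWNTRLKRKLEREWTEENDKRLRDAVFKYG
PHNWRAIASHLPGRTDNEIKNYWWNTRLQRPLER
>C5_anchor1
EWTEEEDKLLREAVEKYGPHNARAIAHHLPQDTDNEIKNYWWNTRFKRKLEREWTEEEDKLLREAVEKYG
PHNWFAIASDLPGRTDNMIKNYWWNTRLKRKLER
>C5_anchor2
EWTEEEDKLLREAVEKYGPHDARAIAHHLPQPTDNEIKNYWWNTRLKRKLEREWTEEEDKLLREAVEKYG
PHNQFAIASDLPGRTDNMIKNYWWNTRLKRKLER
>C7_anchor1
EWTEHEDKLLREAVEKYGPYNWRFIWSHLPGRTDNEIKNYWWNTRLKRKLEREWTEEEDKLLREAVEKYG
YHNWRGIASHLPGRTDNWIKNYWTNYRLKWKLER
>C7_anchor2
EWTEHESKLLHEAVEKYGPHNWRFIWSHLPGRTDNEIKNYWWNTRLKRKLEREWTEEEDKLLREAVEKYG
PHNWRGIASHLPGRTDNWIKNYWTNYRLKWKLER
>C17_anchor1
VWTEEEDKLLREAVEKYGPHNWRAIASHLQGRTDNGIKNYWWNTRLKRKLEREETEEYDKILREYVEKYG
PHNWRAIASHLWGRTNNEIKNYWWNTRLKRKLEA
>C17_anchor2
VWTEEEDKLLREAVEKYGPHNWRAIASHLPGRTDNGIKNYWWNPRLPRKLEREETEEYDKILREYVEKYG
PHNWRAIASHLWGRTNNEIKNYWWNTRLKRKLER
>C20_anchor1
EWTEEEDKLLREAVEKSGPHNWRAIASHLPGRTDNEEKNYWWNERLKRKLEREWTEEEYKLPREAVVHYG
PHNWRAEAKHLPGRTDNEIKNYWWNTRLKRKMER
>C20_anchor2
EWTEEEDKLLREAAEKSGPHNWYAIASHLPGRTDNEEKNYWWNTRLKRKLEREWTEEEYKLPREAVVKYG
PHNWRAEAKHLPGRTDNEIKNYWWNTRLKRKMER
>C22_anchor1
EITEEEDKLLREAVEKYGPHNWRAIASHLPGKTDNEIKEYPWNTRRKRKDEREITEEEDKLLREAVEKYG
PHNWRAIASHLPGRTDREIKNYWWNTCLKRKLER
>C22_anchor2
EITEEEDKLLREAVEKYGPHNWRAIASHLPGKTDNEIKGYPWNTRRKRKDEREWTEEEDKLLREAVWKYG
PHNWRAIASHLPGRTDREIKNYWWNTCLKRKLER
>C27_anchor1
EWTEEEDKLLREAVGKYGPHNWRAIASHLQGRTDNEEKNYWWNTRLKRKLEREMTEEEDRLLEEAVEKYG
PHNDRAIASHLPGRTDNEIKNYWWNTHLRLKLER
>C27_anchor2
EWTEEEDKLLREAVGKYGPHNWRAIASHLQGRTDNEIKNYWWNTRLKRKLEREMTEEEDRLLEEAVLKYG
PHNWRAIASHLPGRTDNEIKNYWWNFHLRLKLER
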