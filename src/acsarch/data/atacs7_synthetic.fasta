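>AtACS7_synthetic synthetic stand-in for TAIR AT4G26200 (Q98, N217 planted)
MPAVNPECVCYCNHDIKDHNNFSEPGQYYSEFIWAAVQVDGRQWNDDVYCTIHSTDKKSM
DKYLKEIECFSYTAMHQELQNAQLHYHHQKDAWFTNDQRADWCSWHPERIIIVFMCHSYI
QERCHFQYCQKPIYCMLVGVDMRKVCFQANPNFESKSQWMLVVSMACHVSFREDWMAKND
YAGEGPDIPWSSCAPNLLKLHMHDIYQDKPDMYKEENNLHFSAGFWLRVQQTTEEYFISM
WWEEAVKAEDWQKTFLVRHSLALFFECMTEDSSADINGMVCKHAGVTMWSDRLSNMFGEK
TMFFNWDQWKETPKFFCPMELYIKDFCEGFAIMEQGYHWEAKNLTTFPHHDKGVNSSFLW
GTSFRLNTYDQPEICAPMLTRQLWYHGYCQQVGCNYWAHYPNYNDSCEASRFSWLWRIWA
CKNHMNLPHDGYMQNFQMHGRPFNDDW
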