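# Piricyclamide core peptides detected in cultured Microcystis strains,
# with the post-translational modifications assigned by LC-MS.
# mods codes: G geranyl, P prenyl, SS disulfide bridge, - none observed.
# columns: core	mods
NEFMQTGSYSGP	G
TFCDLATKQCYP	SS
WILLADGTRPKNAP	-
MSGVDYYNP	G
TLGCMNGTERCLGLP	SS
DWGTFCVQEDGEGNCKEWYEVP	-
DWGTFCVQEDGEGNCKGWYELP	-
GTHLYTITP	P
APLWDLVRWGAP	-
ILGEGEGWNYNP	P
FAIFLLLP	-
YSNVLPP	-
SQWGWRGLSDP	-
GWGTFCVGEDGDGNCEEWYELP	-
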