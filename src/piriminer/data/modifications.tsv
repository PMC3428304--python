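# Post-translational / derivatization mass algebra, per modification instance.
# "add" and "remove" are elemental formulas applied to the peptide composition.
# disulfide: oxidative bridge between two cysteines (-2H).
# cam_cys: carbamidomethylation of one free cysteine thiol (iodoacetamide);
#   on a formerly disulfide-bridged peptide the bridge is dropped (its -2H is
#   simply not applied), so SS -> 2x cam_cys gains 2H + 2(C2H3NO) = 116 Da nominal.
# met_sulfoxide: sample-preparation oxidation of methionine (+O, +16 nominal).
# columns: name	add	remove
prenyl	C5H8	-
geranyl	C10H16	-
disulfide	-	H2
met_sulfoxide	O	-
cam_cys	C2H3NO	-
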