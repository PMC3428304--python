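# Piricyclamide precursor core peptides from a 122-clone lake-bloom
# metagenome library: 19 unique cores with clone counts.
# columns: clones	core
38	APLWDLVRWGAP
21	DWGTFCVQEDGEGNCKEWYELP
15	TGNKSGKVTP
9	QTIGYWKDP
7	MSGVDYYNP
5	HQSLWAWNGSDP
4	GSGHPLYP
4	TVFDYTVP
4	HQWGWLVGGTDP
3	TRGCSFCPFP
2	FITWSWSIP
2	FTFPPFPPIGP
2	WVNRRIP
1	SWNIDWEYYGLSFPLSP
1	TAFDYTVP
1	FEFLGLRLP
1	TKYGYMFGTP
1	IYNGDGQPYFTLTAFYP
1	IWNQQKGRWEYIFATP
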