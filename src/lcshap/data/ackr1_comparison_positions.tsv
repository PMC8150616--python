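# The four ACKR1 positions used for archaic-sample comparison, GRCh38
# chromosome 1: the GATA-box promoter site, two intron-1 sites and the
# Fy(a/b) site.  CDS-style labels per NM_002036.2; intron positions are
# offsets from the last base of exon 1 (c.21).
# position<TAB>genomic_pos<TAB>label<TAB>ref_base
position	159204893	c.-67	T
position	159205095	c.21+115	T
position	159205215	c.21+235	T
position	159205564	c.125	G
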