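# Duffy (FY) allele definitions over the ACKR1 gene, GRCh38 chromosome 1.
#
# 15 diagnostic exonic positions, 5'->3', with CDS-style labels numbered
# from the first base of the NM_002036.2 coding sequence.  The GATA-box
# promoter position c.-67 (rs2814778) and the Fy(a/b) position c.125
# (rs12075) are anchored to their dbSNP GRCh38 coordinates; the remaining
# 13 coordinates are self-consistent placeholders inside the exon bounds
# (offsets from c.125), pending curation, and carry the shared reference
# bases all three common alleles agree on.  Classification reads only
# these configured positions; intronic and undiagnostic variation is
# ignored by design.
#
# position<TAB>genomic_pos<TAB>label<TAB>ref_base
position	159204893	c.-67	T
position	159205564	c.125	G
position	159205704	c.265	C
position	159205725	c.286	C
position	159205737	c.298	G
position	159205743	c.304	C
position	159205775	c.336	G
position	159205834	c.395	C
position	159205887	c.448	C
position	159205948	c.509	G
position	159206005	c.566	C
position	159206055	c.616	G
position	159206154	c.715	G
position	159206259	c.820	G
position	159206340	c.901	C
#
# allele<TAB>name<TAB>motif (one base per position, 5'->3')
# FY*01 (Fya) is the reference motif; FY*02 (Fyb) differs at c.125G>A;
# FY*02N.01 (Duffy-null) adds the GATA-box c.-67T>C on the FY*02 background.
allele	FY*01	TGCCGCGCCGCGGGC
allele	FY*02	TACCGCGCCGCGGGC
allele	FY*02N.01	CACCGCGCCGCGGGC
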