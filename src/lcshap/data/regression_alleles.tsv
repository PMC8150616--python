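# Toy allele config for the bundled regression fixture (chr1:1-900 toy
# region, gene 380-520).  Two diagnostic positions at in-gene variant
# sites; three motifs exercise reference, single-variant and
# double-variant calls.  Fixture-scale stand-in, not a real gene.
position	395	c.10	T
position	470	c.85	G
allele	TOY*01	TG
allele	TOY*02	AG
allele	TOY*03	AC
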