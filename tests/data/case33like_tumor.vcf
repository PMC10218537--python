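##fileformat=VCFv4.2
##contig=<ID=chr13,length=115169878>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol from annotation">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="deleterious|tolerated|unknown">
##INFO=<ID=ORIGIN,Number=1,Type=String,Description="germline|somatic|unknown">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth at the site">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	tumor
chr13	48941648	.	G	A	.	.	GENE=RB1;EFFECT=deleterious;ORIGIN=somatic	DP:AD	250:148,102
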