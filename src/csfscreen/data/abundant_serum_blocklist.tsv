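# Abundant serum proteins prone to non-specific binding to protein-G beads.
# Eight families: hemoglobin, haptoglobin, hemopexin, immunoglobulins,
# keratins, apolipoproteins, serum albumin, complement.
# Format: match_type<TAB>pattern
name_substring	hemoglobin
name_substring	haptoglobin
name_substring	hemopexin
name_substring	immunoglobulin
name_substring	keratin
name_substring	apolipoprotein
name_substring	albumin
name_substring	complement
gene_prefix	HB
gene_prefix	HP
gene_prefix	HPX
gene_prefix	IGH
gene_prefix	IGK
gene_prefix	IGL
gene_prefix	KRT
gene_prefix	APO
gene_prefix	ALB
gene_prefix	C1Q
gene_prefix	C1R
gene_prefix	C1S
gene_prefix	C2
gene_prefix	C3
gene_prefix	C4
gene_prefix	C5
gene_prefix	C6
gene_prefix	C7
gene_prefix	C8
gene_prefix	C9
gene_prefix	CFB
gene_prefix	CFH
gene_prefix	CFI
gene_prefix	CFD
gene_prefix	CFP
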