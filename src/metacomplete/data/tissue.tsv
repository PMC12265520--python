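pattern_type	pattern	canonical_label
tag	tissue
tag	tissue type
tag	tissue/cell type
tag	cell type
tag	cell line
tag	cell subtype
tag	organ
tag	organism part
tag	body site
tag	anatomical site
tag	source tissue
value	^(whole )?blood$	blood
value	^peripheral blood( mononuclear cells?)?$	blood
value	^pbmcs?$	blood
value	^liver( biopsy| tissue)?$	liver
value	^brain( tissue)?$	brain
value	^(cerebral )?cortex$	brain
value	^hippocampus$	brain
value	^heart( tissue)?$	heart
value	^(left |right )?ventricle$	heart
value	^lung( tissue)?$	lung
value	^kidney( tissue)?$	kidney
value	^spleen$	spleen
value	^skeletal muscle$	muscle
value	^muscle$	muscle
value	^skin$	skin
value	^bone marrow$	bone marrow
value	^(colon|colonic mucosa)$	colon
value	^(small )?intestine$	intestine
value	^pancreas$	pancreas
value	^(mammary gland|breast)$	breast
value	^adipose( tissue)?$	adipose
value	^(tumor|tumour)( tissue)?$	tumor
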