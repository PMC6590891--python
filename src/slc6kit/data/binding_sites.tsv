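# Structural-template binding-site residues for the SLC6/LeuT fold.
# Columns: template_id, site_name, template_pos (1-based), expected_residue.
# LeuT positions follow PDB 2A65 chain A numbering; SERT positions follow
# RefSeq NP_001036.1 numbering.
# The "pocket" siteset is PROVISIONAL: a transcription of the canonical
# occluded-state leucine-pocket residues of LeuT assembled from the
# published structure descriptions, not from a machine-readable table.
template_id	site_name	template_pos	expected_residue
LeuT	Na1	22	A
LeuT	Na1	24	G
LeuT	Na1	27	N
LeuT	Na1	254	T
LeuT	Na2	20	G
LeuT	Na2	23	V
LeuT	Na2	351	A
LeuT	Na2	354	T
LeuT	Na2	355	S
SERT	Cl	121	Y
SERT	Cl	336	S
SERT	Cl	368	N
SERT	Cl	372	S
LeuT	pocket	22	A
LeuT	pocket	26	G
LeuT	pocket	104	V
LeuT	pocket	108	Y
LeuT	pocket	253	F
LeuT	pocket	254	T
LeuT	pocket	256	S
LeuT	pocket	259	F
LeuT	pocket	355	S
LeuT	pocket	359	I
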