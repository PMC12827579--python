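ligand	receptor
HLA-A	CD3D
HLA-A	CD3G
HLA-B	CD3D
HLA-B	CD3G
HLA-C	CD3D
HLA-C	CD3G
B2M	CD3D
B2M	CD3G
VIM	CD44
CD40LG	CD40
ICAM1	ITGAL
CD80	CD28
CD86	CD28
CXCL13	CXCR5
IL21	IL21R
TNF	TNFRSF1A
LTB	LTBR
CCL19	CCR7
CCL21	CCR7
SELL	SELPLG
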