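# Synthetic stand-in for transcriptome-deconvolution-derived relative
# immune-cell abundances (metastasis : matched primary tumor).
# Encodes the qualitative pattern of reduced lymphocyte content in
# metastatic lesions with wide tolerance bands; it is NOT derived from any
# expression dataset.  MDSC rows are monocyte-proxied by convention.
# tolerance = half-width of the acceptable band on the natural-log ratio.
cell_type,site,estimator,ratio,tolerance
tcyt,lung,synthetic_a,0.55,0.7
tcyt,lung,synthetic_b,0.65,0.7
th,lung,synthetic_a,0.60,0.7
treg,lung,synthetic_b,0.75,0.7
m1,lung,synthetic_a,0.85,0.7
m2,lung,synthetic_b,1.20,0.7
mdsc,lung,synthetic_a,1.10,0.7
apc,lung,synthetic_b,0.70,0.7
tcyt,other,synthetic_a,0.45,0.7
tcyt,other,synthetic_b,0.55,0.7
th,other,synthetic_a,0.50,0.7
treg,other,synthetic_b,0.70,0.7
m1,other,synthetic_a,0.80,0.7
m2,other,synthetic_b,1.30,0.7
mdsc,other,synthetic_a,1.15,0.7
apc,other,synthetic_b,0.65,0.7
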