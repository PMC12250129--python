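# ICRP-60 tissue weighting factors (external standard constants, editable).
# REMAINDER applies to the mass-weighted mean dose of unlisted tissues.
tissue,wT
gonads,0.20
red_marrow,0.12
colon,0.12
lung,0.12
stomach,0.12
bladder,0.05
breast,0.05
liver,0.05
oesophagus,0.05
thyroid,0.05
skin,0.01
bone_surface,0.01
REMAINDER,0.05
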