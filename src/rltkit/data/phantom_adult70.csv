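# Reference adult male phantom organ masses (g), 70 kg total body.
# External standard constants (ICRP reference-man style values), editable;
# these are not experimental data from any single study.
organ,mass_g
blood,5500
heart,330
liver,1800
spleen,180
lung,1000
kidney,310
muscle,28000
brain,1400
bone,10500
small_intestine,640
TOTAL_BODY_KG,70
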