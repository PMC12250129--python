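# Nominal dissected-sample masses (g) for an adult mouse necropsy.
# Declared fixture values used by the synthetic worksheet generator;
# not measurements from any particular animal.
organ,mass_g
tumor,0.3
kidney,0.4
blood,1.4
muscle,0.1
liver,1.3
spleen,0.1
lung,0.15
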