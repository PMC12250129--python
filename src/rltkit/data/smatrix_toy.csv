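# Toy S-matrix for Lu-177, mGy/(MBq*h), synthetic fixture.
# Self-dose terms follow the electron-only closed-form
#   S_self = 0.5767 * E_beta(MeV) / m(kg)
# with E_beta = 0.1335 MeV and the packaged phantom masses; cross terms are
# a uniform nominal photon contribution.  These are NOT phantom Monte-Carlo
# values and are intended for demonstrations and tests only.
target,source,S_mGy_per_MBq_h
kidney,kidney,0.248355
kidney,liver,0.0001
kidney,spleen,0.0001
kidney,lung,0.0001
kidney,blood,0.0001
kidney,muscle,0.0001
kidney,remainder,0.0001
liver,kidney,0.0001
liver,liver,0.042772
liver,spleen,0.0001
liver,lung,0.0001
liver,blood,0.0001
liver,muscle,0.0001
liver,remainder,0.0001
spleen,kidney,0.0001
spleen,liver,0.0001
spleen,spleen,0.427717
spleen,lung,0.0001
spleen,blood,0.0001
spleen,muscle,0.0001
spleen,remainder,0.0001
lung,kidney,0.0001
lung,liver,0.0001
lung,spleen,0.0001
lung,lung,0.076989
lung,blood,0.0001
lung,muscle,0.0001
lung,remainder,0.0001
blood,kidney,0.0001
blood,liver,0.0001
blood,spleen,0.0001
blood,lung,0.0001
blood,blood,0.013998
blood,muscle,0.0001
blood,remainder,0.0001
muscle,kidney,0.0001
muscle,liver,0.0001
muscle,spleen,0.0001
muscle,lung,0.0001
muscle,blood,0.0001
muscle,muscle,0.002750
muscle,remainder,0.0001
remainder,kidney,0.0001
remainder,liver,0.0001
remainder,spleen,0.0001
remainder,lung,0.0001
remainder,blood,0.0001
remainder,muscle,0.0001
remainder,remainder,0.001283
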