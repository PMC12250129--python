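name,half_life_days,beta_mean_MeV,photon_keV_yield
Lu-177,6.73,0.1335,208:0.11;113:0.06
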