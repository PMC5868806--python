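taxon,food,tissue_umol,respiration_umol,calcification_umol,added_umol
coral,bacteria,14.8,256.1,2.3,8125
coral,algae,9.4,98.5,3.1,2708
sponge,bacteria,37.2,308.2,0,8125
sponge,algae,8.0,210.7,0,2708
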