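# Receptor -> neurotransmitter family map (version 1).
# Families follow the standard autoradiography-atlas grouping.
glutamate: [AMPA, NMDA, kainate]
GABA: [GABAA, GABAB, Bz]
acetylcholine: [M1, M2, M3, alpha4beta2]
noradrenaline: [alpha1, alpha2]
serotonin: [5HT1A, 5HT2]
dopamine: [D1]
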