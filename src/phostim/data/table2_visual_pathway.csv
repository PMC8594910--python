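# Transcription of the source study's printed Table II: simulated current
# density (mA/m^2) in the visual pathway at 0.5 mA injected current.
# LGN = lateral geniculate nucleus, OC = occipital cortex. PT medians in uA.
montage,median_pt_uA,right_lgn,left_lgn,right_oc,left_oc
Fp2-So,75,16.9,18.8,10.2,10.1
F7-F8,100,24.0,18.7,10.9,8.2
So-rS,125,8.7,17.4,11.0,11.3
Cz-F8,125,35.5,16.0,19.7,19.6
Fp2-Cz,175,24.1,15.8,17.5,17.5
Fp2-rS,175,24.8,36.5,21.2,21.5
Fp2-O2,200,19.8,21.8,79.8,42.0
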