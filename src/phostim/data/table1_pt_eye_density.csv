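# Transcription of the source study's printed Table I: phosphene thresholds (uA)
# and simulated average current density of the right eye (mA/m^2) under both
# volume-conductor models ("brain model" = coarse eye, complete-electrode BC;
# "eye model" = compartmental eye, Neumann BC). One row per electrode montage.
montage,median_pt_uA,mean_pt_uA,sd_pt_uA,eye_density_brain_model,eye_density_eye_model
Fp2-So,75,112,80,138.1,186.7
F7-F8,100,95,33,43.1,38.5
So-rS,125,127,64,77.7,108.0
Cz-F8,125,148,89,41.4,32.5
Fp2-rS,175,183,104,100.7,103.0
Fp2-Cz,175,190,108,98.6,89.4
Fp2-O2,200,187,107,100.2,95.3
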