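# Transcription of the source study's Fig. 4 caption: eye-model current
# densities (mA/m^2) of the five unilateral eye-specific montages, regressed
# there against mean phosphene thresholds. Note Fp2-O2 is printed as 95.4 in
# the caption but 95.3 in Table I; both transcriptions are kept, flagged here.
montage,eye_density_eye_model
Fp2-So,186.7
So-rS,108.0
Fp2-rS,103.0
Fp2-Cz,89.4
Fp2-O2,95.4
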