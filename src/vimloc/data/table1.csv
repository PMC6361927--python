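subject_id,hemisphere,vim_manual_mm3,vim_manual_pct,vim_multiatlas_mm3,vim_multiatlas_pct,vlv_cm3,vlv_pct
YS1,left,,,,,1.1,15
YS1,right,77.6,1,,,1,14
YS2,left,76.3,1,66.9,0.9,1.3,17
YS2,right,82,1.1,71.6,1,1.3,18
YS3,left,83.3,1.5,28.5,0.5,1.1,18
YS3,right,82.9,1.2,44.4,0.6,1.1,16
YS4,left,82.8,1.1,42.4,0.6,1,14
YS4,right,73,1.1,42.4,0.6,0.9,15
YS5,left,67.2,1,43,0.6,1.2,19
YS5,right,78.7,1,41.5,0.5,1,15
ES1,left,93,1.2,42.7,0.6,0.9,13
ES1,right,94.5,1.3,23.7,0.3,0.8,13
ES2,left,58,0.5,19.4,0.2,1.4,14
ES2,right,56.5,0.5,44.9,0.4,1.4,15
ES3,left,81.5,0.9,32.4,0.4,1.2,15
ES3,right,65.5,0.8,9.7,0.1,1,14
ES4,left,71.4,1.1,20.2,0.3,0.7,13
ES4,right,69.1,1,6.1,0.1,0.8,13
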