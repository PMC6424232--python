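patient_id,reference,ki_baseline,suv_max_baseline,suv_mean_baseline,ki_week8,suv_max_week8,suv_mean_week8,ki_pct_change,suv_max_pct_change,suv_mean_pct_change
PD-1,PD,0.033,25.7,12.0,0.075,37.1,16.9,145.0,58.8,51.8
PD-2,PD,0.071,32.6,20.2,0.091,32.6,19.6,38.6,2.1,3.3
PD-3,PD,0.047,49.6,21.9,0.121,85.9,46.8,140.2,63.2,98.4
PD-4,PD,0.083,30.7,19.4,0.110,44.0,23.1,34.9,43.0,20.4
NPD-1,non-PD,0.067,25.8,11.7,0.063,25.74,12.72,-4.7,-4.1,9.4
NPD-2,non-PD,0.145,60.9,34.4,0.121,46.96,26.64,-14.5,-20.0,-20.7
NPD-3,non-PD,0.078,37.6,21.7,0.076,26.70,16.72,-1.3,-28.0,-23.1
NPD-4,non-PD,0.045,38.8,19.8,0.036,30.38,15.47,-19.8,-21.7,-21.8
NPD-5,non-PD,0.051,26.1,14.4,0.051,27.35,15.40,5.4,12.3,11.4
NPD-6,non-PD,0.040,12.4,25.3,0.079,37.59,18.77,97.5,48.2,50.8
NPD-7,non-PD,0.055,25.0,14.8,0.063,34.73,18.31,15.6,32.5,23.0
NPD-8,non-PD,0.059,27.6,13.4,0.051,23.68,14.02,10.1,30.1,30.5
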