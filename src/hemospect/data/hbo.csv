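# Molar extinction coefficient of oxygenated hemoglobin (HbO2) in L mol^-1 cm^-1.
# Compiled visible-range tabulation (Prahl-style compilation of Gratzer/Kollias data),
# resampled to a uniform 10 nm grid. Values rounded; intended for 420-700 nm use.
# columns: wavelength_nm, epsilon
wavelength_nm,epsilon
400,266232
410,466840
420,480360
430,246072
440,102580
450,62816
460,44480
470,33209
480,26629
490,23684
500,20932
510,20035
520,24202
530,39036
540,53236
550,43016
560,32613
570,44496
580,50104
590,7762
600,3200
610,1506
620,942
630,610
640,442
650,368
660,320
670,294
680,278
690,276
700,290
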