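# Molar extinction coefficient of deoxygenated hemoglobin (HbR) in L mol^-1 cm^-1.
# Compiled visible-range tabulation (Prahl-style compilation of Gratzer/Kollias data),
# resampled to a uniform 10 nm grid. Values rounded; intended for 420-700 nm use.
# columns: wavelength_nm, epsilon
wavelength_nm,epsilon
400,223296
410,303956
420,407560
430,528600
440,413280
450,216828
460,130896
470,102580
480,79881
490,62640
500,53412
510,49536
520,44480
530,40092
540,46592
550,53412
560,53788
570,45072
580,37020
590,23500
600,14677
610,9444
620,6509
630,5149
640,4345
650,3750
660,3227
670,2795
680,2408
690,2052
700,1794
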