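# Molar extinction coefficient of methemoglobin (metHb, aquomet form near neutral pH)
# in L mol^-1 cm^-1. Compiled visible-range tabulation (Zijlstra-style multicomponent
# spectrophotometry data), resampled to a uniform 10 nm grid. Shows the broad band
# around 500 nm and the characteristic 630 nm band of acid methemoglobin.
# columns: wavelength_nm, epsilon
wavelength_nm,epsilon
400,150000
410,110000
420,58000
430,30000
440,18500
450,13500
460,10800
470,9600
480,9200
490,9500
500,9900
510,9500
520,8800
530,8100
540,7600
550,6900
560,6200
570,5600
580,5100
590,4600
600,4300
610,4100
620,4050
630,4200
640,3100
650,1600
660,1000
670,800
680,700
690,620
700,560
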