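# Melanosome absorption spectrum in cm^-1 at 100 vol.% melanosome volume fraction.
# Jacques-style power law mu_a = 6.6e11 * lambda_nm^-3.33 (cm^-1), tabulated on a
# uniform 10 nm grid. Strictly decreasing with wavelength across the visible range.
# Units differ from the hemoglobin tables: this column is an absorption-equivalent
# coefficient per unit volume fraction, not a molar extinction coefficient.
# columns: wavelength_nm, epsilon
wavelength_nm,epsilon
400,1427.86
410,1315.15
420,1213.73
430,1122.26
440,1039.55
450,964.60
460,896.52
470,834.56
480,778.06
490,726.43
500,679.16
510,635.82
520,596.01
530,559.38
540,525.62
550,494.47
560,465.67
570,439.02
580,414.31
590,391.39
600,370.08
610,350.26
620,331.80
630,314.59
640,298.51
650,283.49
660,269.44
670,256.28
680,243.94
690,232.37
700,221.50
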