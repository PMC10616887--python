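# Optical basis spectra for the 460-590 nm analysis grid, as published:
#   mua_melanosome  - absorption coefficient (cm^-1) of a melanosome, i.e. the
#                     epidermis at 100 vol.% melanin (follows the ~lambda^-3.48
#                     melanosome power law);
#   mua_oxyblood    - absorption coefficient (cm^-1) of fully oxygenated whole
#                     blood (150 g/L hemoglobin, 2.32e-3 M);
#   mua_deoxyblood  - absorption coefficient (cm^-1) of fully deoxygenated
#                     whole blood (note the single ~555 nm peak and the
#                     isosbestic crossings with oxyblood at 570 and ~585 nm);
#   eps_bilirubin   - molar extinction coefficient (cm^-1 M^-1) of bilirubin
#                     (peak at/below 460 nm, negligible beyond ~530 nm);
#   musp            - reduced scattering coefficient (cm^-1) of skin.
wavelength_nm,mua_melanosome,mua_oxyblood,mua_deoxyblood,eps_bilirubin,musp
460,896.52077,240.192,126.29952,52924.25352,64.94
470,834.56097,179.32968,87.24456,44859.32394,60.61
480,778.05557,143.79768,78.57,29928.05634,56.69
490,726.42535,127.89576,90.0936,14964.80282,53.13
500,679.16269,113.03712,112.6548,5564.21127,49.88
510,635.82156,108.19008,139.17744,1586.14085,46.93
520,596.00898,130.69296,170.58384,429.1831,44.22
530,559.37788,215.76672,210.79656,145.14085,41.74
540,525.62101,287.4744,251.5968,77.90141,39.46
550,494.46571,232.2864,288.4248,56.32394,37.36
560,465.66951,176.11128,290.4552,45.35992,35.43
570,439.01632,240.2784,243.3888,38.72665,33.64
580,414.31315,270.5616,199.908,34.71357,31.99
590,391.38731,77.76432,152.95176,32.28657,30.46
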