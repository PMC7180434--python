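# Molar extinction coefficients of human oxy- and deoxy-hemoglobin, base-10
# convention, units cm^-1 M^-1 (per mole of hemoglobin monomer / heme).
# Values follow the widely used compiled whole-blood spectra (rounded to the
# nearest 1 cm^-1 M^-1, resampled to a 10 nm grid over 650-1000 nm).
# mu_a = ln(10) * eps * C for concentration C in mol/L.
wavelength_nm,eps_hbo2,eps_hb
650,368,3750
660,320,3227
670,294,2795
680,278,2408
690,276,2052
700,290,1794
710,314,1540
720,348,1326
730,390,1102
740,446,1116
750,518,1405
760,586,1549
770,650,1312
780,710,1075
790,774,891
800,816,762
810,864,717
820,916,694
830,974,693
840,1022,692
850,1058,691
860,1092,691
870,1124,698
880,1154,726
890,1178,744
900,1198,762
910,1216,780
920,1234,797
930,1240,820
940,1214,866
950,1196,890
960,1170,908
970,1140,920
980,1110,940
990,1080,970
1000,1058,996
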