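# Synthetic compilation of molar extinction coefficients of human oxy- and
# deoxyhemoglobin (decadic convention, cm^-1 M^-1).  Values reproduce the
# magnitudes and spectral shape of the standard tabulated compilations used
# in tissue oximetry (isosbestic point near 800 nm, well-separated
# coefficients at 740 and 850 nm); they are bundled for self-contained
# simulation and round-trip work, not as a metrological reference.
# wavelength_nm	eps_hbo2	eps_hb
600	3200.0	14677.0
610	1506.0	9443.0
620	942.0	6509.0
630	610.0	5149.0
640	442.0	4345.0
650	368.0	3750.0
660	320.0	3227.0
670	294.0	2795.0
680	277.0	2407.0
690	276.0	2052.0
700	290.0	1794.0
710	314.0	1540.0
720	348.0	1325.0
730	390.0	1102.0
740	446.0	1116.0
750	518.0	1405.0
760	586.0	1549.0
770	650.0	1244.0
780	710.0	1075.0
790	774.0	904.0
800	816.0	762.0
810	864.0	718.0
820	916.0	693.0
830	974.0	693.0
840	1022.0	693.0
850	1058.0	691.0
860	1087.0	692.0
870	1110.0	694.0
880	1128.0	697.0
890	1144.0	702.0
900	1198.0	709.0
910	1220.0	718.0
920	1232.0	728.0
930	1240.0	740.0
940	1214.0	754.0
950	1204.0	769.0
960	1186.0	786.0
970	1162.0	805.0
980	1134.0	825.0
990	1102.0	846.0
1000	1058.0	870.0
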