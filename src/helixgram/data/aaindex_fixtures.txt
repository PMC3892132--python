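H FAUJ880103
D Normalized van der Waals volume (Fauchere et al., 1988)
R PMID:3209351
A Fauchere, J.L., Charton, M., Kier, L.B., Verloop, A. and Pliska, V.
T Amino acid side chain parameters for correlation studies in biology and
  pharmacology
J Int. J. Peptide Protein Res. 32, 269-278 (1988)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.00    6.13    2.95    2.78    2.43    3.95    3.78    0.00    4.66    4.00
    4.00    4.77    4.43    5.89    2.72    1.60    2.60    8.08    6.47    3.00
//
H BIOV880101
D Information value for accessibility; average fraction 35% (Biou et al., 1988)
R PMID:3244698
A Biou, V., Gibrat, J.F., Levin, J.M., Robson, B. and Garnier, J.
T Secondary structure prediction: combination of three different methods
J Protein Engineering 2, 185-191 (1988)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     16.    -70.    -74.    -78.    168.    -73.   -106.    -13.     50.    151.
    145.   -141.    124.    189.    -20.    -70.    -38.    145.     53.    123.
//
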