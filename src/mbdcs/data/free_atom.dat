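# Free-atom reference data for Drude-oscillator parametrization.
# Columns: symbol  alpha_free [Bohr^3]  C6_free [Hartree*Bohr^6]  R_vdw [Bohr]
# Static dipole polarizabilities and C6 coefficients from the Chu & Dalgarno
# compilation (J. Chem. Phys. 121, 4083 (2004)) as adopted by the
# Tkatchenko-Scheffler scheme (PRL 102, 073005 (2009)); van der Waals radii
# from the same scheme.
H    4.50     6.50    3.10
He   1.38     1.46    2.65
Li  164.20  1387.00   4.16
Be   38.00   214.00   4.17
B    21.00    99.50   3.89
C    12.00    46.60   3.59
N     7.40    24.20   3.34
O     5.40    15.60   3.19
F     3.80     9.52   3.04
Ne    2.67     6.38   2.91
Na  162.70  1556.00   3.73
Mg   71.00   627.00   4.27
Al   60.00   528.00   4.33
Si   37.00   305.00   4.20
P    25.00   185.00   4.01
S    19.60   134.00   3.86
Cl   15.00    94.60   3.71
Ar   11.10    64.30   3.55
K   292.90  3897.00   3.71
Ca  160.00  2221.00   4.65
Br   20.00   162.00   3.93
Kr   16.80   129.60   3.82
I    35.00   385.00   4.17
Xe   27.30   285.90   4.00
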