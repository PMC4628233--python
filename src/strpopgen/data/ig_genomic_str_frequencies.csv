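locus,allele,freq_eu,freq_usa
FH2054,152,0.0,0.002
FH2054,156,0.06,0.01
FH2054,160,0.12,0.1
FH2054,164,0.07,0.09
FH2054,168,0.42,0.18
FH2054,172,0.28,0.34
FH2054,176,0.06,0.24
FH2054,180,0.0,0.03
FH2054,184,0.0,0.01
AHTh171-A,219,0.02,0.01
AHTh171-A,225,0.02,0.03
AHTh171-A,227,0.16,0.37
AHTh171-A,233,0.0,0.002
AHTh171-A,235,0.01,0.01
AHTh171-A,237,0.79,0.58
FH2001,132,0.3,0.1
FH2001,136,0.01,0.01
FH2001,140,0.003,0.0
FH2001,144,0.1,0.06
FH2001,148,0.58,0.81
FH2001,152,0.01,0.03
REN169D01,202,0.1,0.11
REN169D01,210,0.06,0.22
REN169D01,212,0.04,0.02
REN169D01,214,0.003,0.002
REN169D01,216,0.28,0.43
REN169D01,220,0.52,0.22
AHTH130,119,0.41,0.29
AHTH130,121,0.27,0.2
AHTH130,127,0.15,0.24
AHTH130,129,0.01,0.15
AHTH130,131,0.06,0.01
AHTH130,137,0.11,0.11
AHTH130,141,0.0,0.002
INU005,106,0.02,0.0
INU005,120,0.01,0.01
INU005,122,0.01,0.0
INU005,124,0.47,0.5
INU005,126,0.29,0.43
INU005,128,0.0,0.002
INU005,130,0.19,0.05
INU005,132,0.01,0.002
AHT137,131,0.03,0.09
AHT137,133,0.1,0.09
AHT137,135,0.0,0.01
AHT137,137,0.23,0.07
AHT137,141,0.09,0.09
AHT137,143,0.43,0.38
AHT137,147,0.12,0.21
AHT137,151,0.003,0.08
INU055,204,0.09,0.04
INU055,210,0.47,0.24
INU055,214,0.13,0.55
INU055,218,0.31,0.17
INU055,222,0.0,0.002
REN169O18,162,0.52,0.13
REN169O18,164,0.2,0.07
REN169O18,166,0.06,0.002
REN169O18,168,0.19,0.41
REN169O18,170,0.03,0.38
FH2848,228,0.04,0.01
FH2848,232,0.07,0.0
FH2848,236,0.08,0.03
FH2848,238,0.2,0.22
FH2848,240,0.41,0.71
FH2848,244,0.21,0.03
REN105L03,227,0.06,0.06
REN105L03,229,0.01,0.0
REN105L03,231,0.32,0.15
REN105L03,233,0.59,0.5
REN105L03,239,0.003,0.0
REN105L03,241,0.02,0.3
REN54P11,222,0.06,0.19
REN54P11,226,0.0,0.02
REN54P11,228,0.12,0.02
REN54P11,232,0.46,0.34
REN54P11,234,0.07,0.0
REN54P11,238,0.29,0.42
REN64E19,139,0.07,0.01
REN64E19,143,0.39,0.51
REN64E19,145,0.24,0.25
REN64E19,147,0.15,0.24
REN64E19,149,0.15,0.0
REN247M23,268,0.27,0.33
REN247M23,270,0.33,0.24
REN247M23,272,0.16,0.15
REN247M23,274,0.14,0.28
REN247M23,276,0.11,0.0
AHTk253,286,0.08,0.23
AHTk253,288,0.66,0.56
AHTk253,290,0.09,0.02
AHTk253,292,0.16,0.19
INRA21,95,0.52,0.6
INRA21,97,0.01,0.19
INRA21,99,0.0,0.01
INRA21,101,0.47,0.19
INU030,144,0.22,0.14
INU030,148,0.0,0.01
INU030,150,0.76,0.85
INU030,152,0.02,0.002
C22.279,116,0.11,0.02
C22.279,118,0.003,0.01
C22.279,124,0.89,0.97
C22.279,128,0.0,0.003
LEI004,95,0.58,0.69
LEI004,107,0.42,0.3
LEI004,113,0.0,0.01
REN162C04,202,0.29,0.2
REN162C04,204,0.02,0.01
REN162C04,206,0.69,0.79
AHTk211,87,0.53,0.64
AHTk211,89,0.06,0.01
AHTk211,91,0.14,0.16
AHTk211,95,0.27,0.2
AHT121,96,0.19,0.14
AHT121,98,0.08,0.16
AHT121,100,0.01,0.29
AHT121,102,0.18,0.2
AHT121,104,0.06,0.03
AHT121,106,0.31,0.06
AHT121,108,0.003,0.07
AHT121,110,0.05,0.01
AHT121,112,0.01,0.05
AHT121,114,0.01,0.0
AHTh260,238,0.0,0.01
AHTh260,240,0.29,0.36
AHTh260,242,0.003,0.0
AHTh260,244,0.04,0.04
AHTh260,246,0.29,0.17
AHTh260,248,0.01,0.0
AHTh260,250,0.28,0.01
AHTh260,252,0.003,0.03
AHTh260,254,0.08,0.39
AHTh260,256,0.0,0.002
VGL0910,13,0.21,0.01
VGL0910,14,0.05,0.01
VGL0910,15,0.01,0.04
VGL0910,16,0.003,0.09
VGL0910,17,0.44,0.4
VGL0910,18,0.02,0.07
VGL0910,19,0.17,0.27
VGL0910,20,0.07,0.09
VGL0910,21,0.04,0.02
VGL1063,8,0.046,0.16
VGL1063,11,0.0,0.01
VGL1063,12,0.01,0.003
VGL1063,13,0.28,0.26
VGL1063,14,0.29,0.39
VGL1063,15,0.03,0.01
VGL1063,17,0.003,0.0
VGL1063,18,0.19,0.02
VGL1063,19,0.16,0.14
VGL1063,20,0.01,0.002
VGL1063,31,0.0,0.01
VGL1165,18,0.07,0.0
VGL1165,19,0.37,0.27
VGL1165,20,0.003,0.06
VGL1165,21,0.01,0.02
VGL1165,23,0.04,0.16
VGL1165,24,0.01,0.12
VGL1165,25,0.1,0.16
VGL1165,26,0.01,0.0
VGL1165,29,0.38,0.13
VGL1165,30,0.003,0.09
VGL2918,7,0.026,0.02
VGL2918,12,0.08,0.05
VGL2918,13,0.42,0.072
VGL2918,14,0.03,0.2
VGL2918,15,0.11,0.07
VGL2918,16,0.0,0.003
VGL2918,17,0.003,0.02
VGL2918,18,0.19,0.22
VGL2918,19,0.13,0.01
VGL2918,20,0.01,0.17
VGL2918,21,0.003,0.16
VGL2918,22,0.0,0.01
VGL2918,23,0.0,0.01
VGL0760,19,0.01,0.002
VGL0760,20,0.51,0.07
VGL0760,21,0.28,0.64
VGL0760,22,0.04,0.12
VGL0760,23,0.15,0.17
VGL0760,24,0.003,0.01
VGL0760,25,0.003,0.0
VGL1828,14,0.0,0.02
VGL1828,15,0.03,0.09
VGL1828,16,0.15,0.01
VGL1828,17,0.08,0.11
VGL1828,18,0.14,0.34
VGL1828,19,0.42,0.41
VGL1828,20,0.07,0.02
VGL1828,21,0.12,0.003
VGL2009,9,0.26,0.06
VGL2009,10,0.07,0.27
VGL2009,11,0.1,0.19
VGL2009,13,0.39,0.46
VGL2009,14,0.18,0.02
VGL2009,15,0.01,0.002
VGL2009,16,0.0,0.01
VGL2009,20,0.0,0.002
VGL2409,13,0.03,0.09
VGL2409,15,0.0,0.04
VGL2409,16,0.003,0.03
VGL2409,17,0.14,0.12
VGL2409,18,0.67,0.35
VGL2409,19,0.16,0.365
VGL2409,20,0.0,0.01
VGL2409,21,0.0,0.002
VGL3008,15,0.03,0.22
VGL3008,16,0.22,0.05
VGL3008,17,0.22,0.26
VGL3008,18,0.38,0.2
VGL3008,19,0.15,0.26
VGL3008,20,0.003,0.01
VGL3008,21,0.0,0.01
VGL3235,13,0.003,0.0
VGL3235,14,0.64,0.2
VGL3235,15,0.08,0.15
VGL3235,16,0.0,0.01
VGL3235,17,0.26,0.37
VGL3235,18,0.01,0.25
VGL3235,19,0.003,0.02
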