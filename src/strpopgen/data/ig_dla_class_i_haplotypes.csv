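name,allele1,allele2,allele3,allele4,freq_eu,freq_usa
1008,386,373,289,182,0.03,0.21
1012,388,369,289,188,0.01,0.01
1016,382,371,277,178,0.10,0.06
1030,380,373,293,178,0.01,0.03
1036,389,365,289,180,0.003,0.00
1040,380,371,277,186,0.24,0.04
1044,375,373,291,178,0.32,0.21
1048,380,370,289,184,0.00,0.02
1049,380,370,289,186,0.00,0.002
1050,380,371,289,182,0.00,0.002
1051,380,371,289,184,0.01,0.00
1052,380,372,289,184,0.20,0.19
1053,382,377,277,186,0.03,0.11
1054,382,379,277,184,0.00,0.01
1055,386,373,289,180,0.00,0.002
1056,386,373,289,190,0.01,0.01
1058,387,378,287,186,0.01,0.00
1059,390,371,291,182,0.03,0.09
1065,380,371,277,181,0.003,0.00
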