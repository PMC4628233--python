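name,allele1,allele2,allele3,freq_eu,freq_usa,drb1_dqa1_dqb1
2003,343,324,282,0.01,0.01,01503/00601/02301
2015,339,327,280,0.00,0.002,
2017,343,322,280,0.23,0.22,01101/00201/01303
2023,341,323,282,0.01,0.03,00601/005011/00701
2029,337,324,268,0.03,0.09,02901/00301/00401
2030,339,322,268,0.00,0.002,
2031,339,322,282,0.10,0.06,01301/00101/00201 or dqb002v
2032,339,323,280,0.00,0.09,00101/00101/00201
2033,339,323,282,0.00,0.01,00101/00101/00201
2034,341,322,280,0.32,0.21,00603/00101/00802
2035,341,323,280,0.03,0.13,00601/005011/00701
2036,341,327,276,0.00,0.09,00203/00901/00101
2037,341,327,280,0.00,0.01,00203/00901/00101
2038,345,324,280,0.03,0.00,
2039,345,327,276,0.24,0.05,00201/00901/00101
2040,345,327,280,0.06,0.00,
2041,349,321,280,0.003,0.00,
2044,343,324,268,0.003,0.00,
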