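marker,kind,region,case_homozygous,n_case,control_homozygous,n_control
3CCA,locus,class_I,33,85,23,104
4ACA,locus,class_I,41,85,32,104
4BCT,locus,class_I,40,85,37,104
1131,locus,class_I,37,85,28,104
5ACA,locus,class_II,41,85,35,104
5ACT,locus,class_II,38,85,34,104
5BCA,locus,class_II,51,85,44,104
DLA-I,haplotype,class_I,26,85,18,104
DLA-II,haplotype,class_II,24,85,12,104
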