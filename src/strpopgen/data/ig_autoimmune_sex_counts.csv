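group,disease,incidence,female,male
case,Addison,9,6,3
case,IMHA,30,25,5
case,IMTP,12,9,3
case,IMPA,23,12,11
case,Meningitis,6,4,2
case,Pemphigus,10,7,3
case,Thyroiditis,11,8,3
case,Orchitis,2,,2
case,Total affected,103,60,31
control,Total healthy,104,59,45
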