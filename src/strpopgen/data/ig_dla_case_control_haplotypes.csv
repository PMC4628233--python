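region,name,case_count,control_count
class_I,1008,34,48
class_I,1012,1,3
class_I,1016,6,13
class_I,1030,5,6
class_I,1040,7,7
class_I,1044,35,39
class_I,1048,5,4
class_I,1049,1,0
class_I,1052,26,47
class_I,1053,21,22
class_I,1054,3,2
class_I,1056,1,2
class_I,1059,19,15
class_II,2003,1,3
class_II,2017,33,53
class_II,2023,5,6
class_II,2029,19,15
class_II,2030,0,1
class_II,2031,6,12
class_II,2032,14,19
class_II,2033,3,2
class_II,2034,35,39
class_II,2035,20,29
class_II,2036,15,21
class_II,2037,3,1
class_II,2039,10,7
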