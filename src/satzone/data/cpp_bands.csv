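family,pattern,chr1,chr2,chr3,chr4,chr5,chr6,chr7,chr8,chrX,n_chrom
CpaTR004-335,B,d,d,d,,,d,,d,,5
CpaTR006-11,B,id,id,id,id,d,d,d,d*,id,9
CpaTR007-21,B,id,d,d,id,d,d,d,d,d,9
CpaTR008-331,B,,,,,,d*,d*,,,2
CpaTR009-172,B,,,,,,,i,,,1
CpaTR010-275,DB,,,,,,,i,,,1
CpaTR011-213,B,,p,p*,p,p,p,,p,p,7
CpaTR012-247,B,d,d,d,d,d,d,d,d,,8
CpaTR013-55,B,,,,i,,,,,,1
CpaTR016-7,B,,,,,d,d,d,d,,4
CpaTR017-289,B,,p,d,,,,,,d,3
CpaTR020-246,B,,,,,,,,,pi,1
CpaTR024-210,B,,,,,,pi,p*,p*,,3
CpaTR025-248,B,,,,,,d*,d*,,,2
CpaTR026-239,B,i,,,,,i,,,,2
CpaTR028-148,B,,p,,,,,,p,,2
CpaTR030-79,B,p,p*,p,,,,,,,3
CpaTR032-20,B,,d,d,,,,,,d,3
CpaTR033-222,NS,,,,,,,,,,0
CpaTR034-61,NS,,,,,,,,,,0
CpaTR036-168,B,p,p,p,p,p,p,p*,p,,8
CpaTR039-139,B,,iii,i,,,,,,,2
CpaTR040-161,B,p*i*d*,i,i,p*i*d*,i*,i,,,,6
CpaTR044-205,B,i,,,,,,,,,1
CpaTR046-157,B,p,,p*,,,,,d*,,3
CpaTR047-287,NS,,,,,,,,,,0
CpaTR048-15,B,,,,,,id,,,,1
CpaTR049-215,B,,,i,,,,,,,1
CpaTR050-288,NS,,,,,,,,,,0
CpaTR053-405,B,,,,,,i,,,,1
CpaTR057-102,NS,,,,,,,,,,0
CpaTR058-196,B,,,,,,,,,i,1
CpaTR061-27,B,,,,,,,,,i,1
CpaTR062-56,B,,,,,,,,,p,1
CpaTR063-92,B,,,,,,,,p,,1
CpaTR065-379,B,,,,,,d,,,,1
CpaTR068-155,B,i,,,,,i,,,,2
CpaTR069-89,B,,,,,,i,,,,1
CpaTR074-186,B,,,,,,d,,,,1
CpaTR075-45,B,d*,,,,,,,,,1
CpaTR076-168,NS,,,,,,,,,,0
CpaTR077-16,B,,,,,,id,,,,1
CpaTR091-49,B,,d,,,,,,,,1
CpaTR094-170,NS,,,,,,,,,,0
CpaTR097-108,NS,,,,,,,,,,0
CpaTR100-295,NS,,,,,,,,,,0
CpaTR103-33,NS,,,,,,,,,,0
CpaTR104-269,B,,,,,,d,,,,1
CpaTR107-237,NS,,,,,,,,,,0
CpaTR110-159,B,,,,,,,p*,,,1
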