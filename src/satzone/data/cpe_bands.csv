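family,pattern,chr1,chr2,chr3,chr4,chr5,chr6,chr7,chr8,chrX,n_chrom
CpaTR004-335,B,d,d,d,,,,,,,3
CpaTR006-11,B,d,,id,id,d,d,d,d,i,8
CpaTR007-21,B,d,d*,d,id,d,d,d,d,id,9
CpaTR008-331,B,,,,,,,pd*,,,1
CpaTR009-172,B,,,,,,,i,,,1
CpaTR010-275,DB,,,,,,,i,,,1
CpaTR011-213,B,p,p,p,p,p,p,p,p,p,9
CpaTR012-247,B,d,d,d,d,d,d,d,d,ii,9
CpaTR013-55,NS,,,,,,,,,,0
CpaTR016-7,B,,,,,d,d,d,,,3
CpaTR017-289,B,,p,d,,,,,,,2
CpaTR020-246,B,,,,,,,,,p,1
CpaTR024-210,B,,,,,,pi,p,,,2
CpaTR025-248,NS,,,,,,,,,,0
CpaTR026-239,B,i,,,,,i,i*,,,3
CpaTR028-148,B,,p,,,,,,p,,2
CpaTR030-79,B,p,p,p,,,,,,,3
CpaTR032-20,B,,,d,,,,,,,1
CpaTR033-222,B,d,,,,,,,,,1
CpaTR034-61,B,,,i,,,,,,,1
CpaTR036-168,B,p,p*,p,p*,,i*,,,,5
CpaTR039-139,B,,iii,i,,,,,,,2
CpaTR040-161,B,i,,,p*i*,,,,,,2
CpaTR044-205,B,i,,,,,,,,,1
CpaTR046-157,B,,,p,,,,,,,1
CpaTR047-287,B,,,,,,p*,p*,,i,3
CpaTR048-15,B,,,,,,id,,,,1
CpaTR049-215,B,,,i,,,,,,,1
CpaTR050-288,B,p,,,,,,,,,1
CpaTR053-405,NS,,,,,,,,,,0
CpaTR057-102,B,,,,,,,p,,,1
CpaTR058-196,NS,,,,,,,,,,0
CpaTR061-27,B,,,,,,,,,i,1
CpaTR062-56,B,,,,,,,,,p,1
CpaTR063-92,B,,,,,,,,p,,1
CpaTR065-379,B,,,,,,d,,,,1
CpaTR068-155,B,i*,,,,,i,,,,2
CpaTR069-89,B,,,,,,i,,,,1
CpaTR074-186,B,,,,,,d,,,,1
CpaTR075-45,B,d,d,,,,,,,,2
CpaTR076-168,B,,,,,,,d,,,1
CpaTR077-16,B,,,,,,id,i*,,,2
CpaTR091-49,B,,d,,,,,,,,1
CpaTR094-170,B,,,i,,,,,,,1
CpaTR097-108,B,i,,,,,,,,,1
CpaTR100-295,B,,,,,,,p,,,1
CpaTR103-33,B,d*,,,,,,,,,1
CpaTR104-269,B,,ii*,,,,id*,i*,,i,4
CpaTR107-237,B,,,,,,,p,,,1
CpaTR110-159,B,,,,,,,p,,,1
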