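population,marker,linkage,NN,NB,BB,N,B
ARU,CpaTR100-295,autosomal,13,0,0,,
GAB,CpaTR100-295,autosomal,7,0,0,,
HER,CpaTR100-295,autosomal,6,1,0,,
POR,CpaTR100-295,autosomal,10,1,1,,
CM,CpaTR100-295,autosomal,4,3,1,,
PAZ,CpaTR100-295,autosomal,0,0,10,,
ESC,CpaTR100-295,autosomal,0,0,14,,
ARU,CpaTR104-269,x_linked,,,,8,0
GAB,CpaTR104-269,x_linked,,,,8,0
HER,CpaTR104-269,x_linked,,,,8,0
POR,CpaTR104-269,x_linked,,,,9,0
CM,CpaTR104-269,x_linked,,,,6,4
PAZ,CpaTR104-269,x_linked,,,,0,9
ESC,CpaTR104-269,x_linked,,,,2,7
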