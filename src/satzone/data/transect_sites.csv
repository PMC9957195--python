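population,country,latitude,longitude,altitude_m,n_males,order_index
ARU,France,43.100278,-0.443889,400,41,1
GAB,France,42.900000,-0.433333,1020,7,2
HER,France,42.863000,-0.391778,1209,7,3
POR,France,42.800833,-0.415000,1708,12,4
CM,Spain,42.785944,-0.392889,1569,8,5
PAZ,Spain,42.765972,-0.342750,1343,10,6
ESC,Spain,42.731694,-0.310917,1130,42,7
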