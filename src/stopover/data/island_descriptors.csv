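island,latitude,longitude,long_km,min_dist_africa,str_dist_africa,min_dist_land,min_d_south_land,area,max_alt,ndvi,lcbd,bd_ti,years_used
Aire,39.80,4.29,431.2,321,321,1.1,321,0.307,15,0.239,0.008,0.038,16
Cabrera,39.14,2.95,318.4,258,258,13.7,258,11.53,175,0.274,0.027,0.086,8
Formentera,38.73,1.40,184.7,232,234,2.1,234,83.20,195,0.229,0.012,0.048,7
Colom,39.96,4.28,429.4,341,341,0.28,0.61,0.59,43,0.301,0.008,0.040,5
Columbrets,39.90,0.69,122.1,377,395,50,108,0.14,67,0.144,0.007,0.033,9
Conillera,38.99,1.22,168.4,270,273,1.2,1.2,0.72,59,0.216,0.014,0.059,7
Dragonera,39.58,2.32,262.8,312,326.5,0.8,2.75,2.52,353,0.311,0.029,0.154,5
Grosa,37.73,-0.71,0,193,219,2.4,9.5,0.18,97,0.153,0.009,0.024,7
Tabarca,38.17,-0.47,22.8,228,252,4.8,61.7,0.40,15,0.159,0.017,0.070,10
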