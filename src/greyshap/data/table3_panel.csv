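year,vehicles_1e4,population_1e4,gdp_1e8,freight_1e4t,passengers_1e4,road_km
2002,2053.17,128453,120332.7,1116324,1475257,1765222
2003,2382.93,129227,135822.8,1159957,1464335,1810000
2004,2693.71,129988,159878.3,1244990,1624526,1871000
2005,3159.66,130756,184937.4,1341778,1697381,3345200
2006,3697.35,131448,216314.4,1466347,1860487,3457000
2007,4358.36,132129,265810.3,1639432,2050680,3584000
2008,5099.61,132802,314045.4,1916759,2682114,3730200
2009,6280.61,133474,340902.8,2127834,2779081,3860823
2010,7801.83,134091,401512.8,2448052,3052738,4008229
2011,9356.32,134735,472881.6,2820100,3286220,4106387
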