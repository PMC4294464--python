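year,vehicles_1e4,population_1e4,gdp_1e8,freight_1e4t,passengers_1e4,road_km
2012,10933.09,135404,519470.10,3188475,3557010,4237500
2013,12670.14,136072,568845.21,3076648,1853463,4356200
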