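covariate,correlation_magnitude
vehicles_1e4,0.941
population_1e4,0.987
gdp_1e8,0.971
freight_1e4t,0.951
passengers_1e4,0.974
road_km,0.890
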