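term,coefficient,std_error,t_value,significance
intercept,779909.386,802935.957,0.971,0.403
vehicles_1e4,-9.153,21.124,-0.433,0.694
population_1e4,-5.403,5.943,-0.909,0.430
gdp_1e8,-0.147,0.235,-0.625,0.576
freight_1e4t,0.087,0.141,0.618,0.580
passengers_1e4,-0.028,0.027,-1.054,0.369
road_km,0.003,0.003,1.023,0.382
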