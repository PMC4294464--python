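year,observed,predicted,relative_error_pct
2002,109381,110334,0.871
2003,104372,105103,0.700
2004,99217,97660,1.569
2005,98738,96681,2.083
2006,89455,89975,0.581
2007,81649,83033,1.695
2008,73484,72208,1.736
2009,67159,69830,3.977
2010,65225,64208,1.559
2011,62387,62035,0.564
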