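year,observed,combined,relative_error_pct,verhulst_error_pct,regression_error_pct
2002,109381,109595,0.196,0,0.871
2003,104372,104384,0.011,0.188,0.700
2004,99217,98590,0.632,0.361,1.569
2005,98738,94190,4.606,5.337,2.083
2006,89455,88476,1.094,1.580,0.581
2007,81649,82714,1.304,1.190,1.695
2008,73484,76114,3.579,5.119,1.736
2009,67159,71478,6.431,7.141,3.977
2010,65225,66206,1.504,2.392,1.559
2011,62387,61829,0.894,0.991,0.564
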