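year,observed,predicted,relative_error_pct
2002,109381,109381,0
2003,104372,104176,0.188
2004,99217,98859,0.361
2005,98738,93468,5.337
2006,89455,88042,1.580
2007,81649,82621,1.190
2008,73484,77246,5.119
2009,67159,71955,7.141
2010,65225,66785,2.392
2011,62387,61769,0.991
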