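year,deaths
2002,109381
2003,104372
2004,99217
2005,98738
2006,89455
2007,81649
2008,73484
2009,67159
2010,65225
2011,62387
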