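year,observed,regression_pred,verhulst_pred
2012,59997,62402,52130
2013,56017,73962,47911
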