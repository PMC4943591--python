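topic,year,count,impressions_millions
commercial,2012,53471,59.74
commercial,2013,283677,195.25
commercial,2014,149333,951.03
cessation,2012,6392,8.59
cessation,2013,6599,25.64
cessation,2014,8386,42.72
discount,2012,26596,27.02
discount,2013,112720,38.21
discount,2014,37735,160.49
flavor,2012,1685,2.24
flavor,2013,2715,4.79
flavor,2014,6133,17.51
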