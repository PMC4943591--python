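year,total,automated,organic,discarded,accounts_automated,accounts_organic,accounts_unclassified
2012,107918,85546,13492,8880,12715,12052,19512
2013,426306,339111,76037,11158,64874,59376,120142
2014,316424,234972,68698,12754,54033,63289,48528
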