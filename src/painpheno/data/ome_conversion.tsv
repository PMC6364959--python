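ingredient	route	factor
morphine	oral	1.0
morphine	iv	3.0
oxycodone	oral	1.5
hydrocodone	oral	1.0
codeine	oral	0.15
tramadol	oral	0.1
hydromorphone	oral	4.0
hydromorphone	iv	20.0
fentanyl	iv	100.0
fentanyl	transdermal	7.2
methadone	oral	3.0
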