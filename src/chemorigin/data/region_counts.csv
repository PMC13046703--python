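region,country,n
Yunnan,China,360
Sichuan,China,103
Guizhou,China,157
Chongqing,China,92
Henan,China,206
Hunan,China,103
Fujian,China,124
Shandong,China,24
Heilongjiang,China,100
United States,United States,64
Brazil,Brazil,129
Zimbabwe,Zimbabwe,154
Zambia,Zambia,101
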