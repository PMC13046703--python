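region,component,mean
Hunan,Total alkaloids,3.1
Heilongjiang,Total alkaloids,1.19
Heilongjiang,Reducing sugar,28.5
Hunan,Reducing sugar,16.39
Heilongjiang,Total sugar,33.23
Hunan,Total sugar,17.45
Sichuan,Total nitrogen,2.39
Heilongjiang,Total nitrogen,1.52
Henan,Fru-Asn,4368.55
Hunan,Fru-Asn,2666.5
Heilongjiang,Succinic acid,0.22
Sichuan,Rutin,10.4
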