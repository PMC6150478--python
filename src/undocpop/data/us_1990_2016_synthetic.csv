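year,apprehensions,recidivist_apprehensions,deterrence_rate,dhs_apprehension_rate,visas_issued,deportations,status_adjustments
1990,1103353,,,,5800000,30039,60000
1991,1132033,,,,5900000,33189,62300
1992,1199560,,,,6000000,43671,64600
1993,1263490,,,,6000000,42542,66900
1994,1031668,,,,6000000,45674,69200
1995,1324202,,,,6200000,50924,71500
1996,1549876,,,,6200000,69680,73800
1997,1412953,,,,6000000,114432,76100
1998,1555776,,,,5800000,174813,78400
1999,1537000,,,,6200000,183114,80700
2000,1643679,,,,7100000,188467,83000
2001,1235718,,,,7600000,189026,85300
2002,929809,,,,5800000,165168,87600
2003,905065,,,,4900000,211098,89900
2004,1139282,,,,5000000,240665,92200
2005,1171396,286992,0.3,0.35,5400000,246431,94500
2006,1071972,262419,0.32,0.36,5800000,280974,96800
2007,858638,215346,0.34,0.38,6400000,319382,99100
2008,705005,177661,0.37,0.4,6600000,359795,101400
2009,540865,138570,0.39,0.42,5800000,391597,103700
2010,447731,113589,0.41,0.43,6400000,381738,106000
2011,327577,85891,0.43,0.46,7500000,387134,108300
2012,356873,94429,0.46,0.49,8900000,416324,210600
2013,414397,109898,0.48,0.51,9200000,434015,562900
2014,479371,127033,0.5,0.53,9900000,407075,235200
2015,331333,87472,0.52,0.55,10900000,333341,177500
2016,408870,101195,0.55,,10400000,340056,169800
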