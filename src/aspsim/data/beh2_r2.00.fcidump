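&FCI NORB=6,NELEC=4,MS2=0,
  ORBSYM=1,1,1,1,1,1,
  ISYM=1,
 &END
 3.3881872017949738E-01    1    1    1    1
 3.4438459105172770E-01    1    1    2    2
-3.0471007428613635E-04    1    1    3    1
 3.4244329926229311E-01    1    1    3    3
 3.3416603280308094E-01    1    1    4    4
 3.3416603280308099E-01    1    1    5    5
 8.9505619974304118E-03    1    1    6    2
 3.6085377768860216E-01    1    1    6    6
 1.4488755275215554E-01    2    1    2    1
-9.5050558851133962E-02    2    1    3    2
-3.1714860354769774E-02    2    1    6    1
 1.3127048059161919E-01    2    1    6    3
 3.6989592841877650E-01    2    2    2    2
-4.0274167689320982E-02    2    2    3    1
 3.5546690334615527E-01    2    2    3    3
 2.9756869208468045E-01    2    2    4    4
 2.9756869208468051E-01    2    2    5    5
-2.3454953927012183E-02    2    2    6    2
 3.6889162964878591E-01    2    2    6    6
 9.3776956396188368E-02    3    1    3    1
-2.5159683251002520E-02    3    1    3    3
 8.8056438999513709E-02    3    1    4    4
 8.8056438999513723E-02    3    1    5    5
 8.9072030582998091E-02    3    1    6    2
 3.7998595046255437E-03    3    1    6    6
 1.0297141417385643E-01    3    2    3    2
 6.6545422180003963E-02    3    2    6    1
-9.1204337957537573E-02    3    2    6    3
 3.6121416090318659E-01    3    3    3    3
 3.2210841451187294E-01    3    3    4    4
 3.2210841451187305E-01    3    3    5    5
-2.1027927450455376E-02    3    3    6    2
 3.6777909399669445E-01    3    3    6    6
 4.7282391971367008E-02    4    1    4    1
 4.5051103267484363E-02    4    1    4    3
 9.4447998545870333E-03    4    2    4    2
 1.2247632821051345E-02    4    2    6    4
 4.4264214556583900E-02    4    3    4    3
 4.4985904108667107E-01    4    4    4    4
 4.0136028264432877E-01    4    4    5    5
 8.3929267425197837E-02    4    4    6    2
 3.5801791823284557E-01    4    4    6    6
 4.7282391971367015E-02    5    1    5    1
 4.5051103267484363E-02    5    1    5    3
 9.4447998545870351E-03    5    2    5    2
 1.2247632821051348E-02    5    2    6    5
 4.4264214556583914E-02    5    3    5    3
 2.4249379221171152E-02    5    4    5    4
 4.4985904108667119E-01    5    5    5    5
 8.3929267425197879E-02    5    5    6    2
 3.5801791823284568E-01    5    5    6    6
 5.8519574806008140E-02    6    1    6    1
-3.4299348928258325E-02    6    1    6    3
 9.5282318669288782E-02    6    2    6    2
 2.0389357154617243E-02    6    2    6    6
 1.2748191195457956E-01    6    3    6    3
 1.7352003930058636E-02    6    4    6    4
 1.7352003930058639E-02    6    5    6    5
 4.0515325959020032E-01    6    6    6    6
-1.2371715392180558E+00    1    1    0    0
-1.2137228044463071E+00    2    2    0    0
-1.4197513400403834E-02    3    1    0    0
-9.9369751363040304E-01    3    3    0    0
-9.9896147143996306E-01    4    4    0    0
-9.9896147143996317E-01    5    5    0    0
-2.6161030441892285E-02    6    2    0    0
-8.6513856205390793E-01    6    6    0    0
-1.2249106552517166E+01    0    0    0    0
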