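&FCI NORB=6,NELEC=4,MS2=0,
  ORBSYM=1,1,1,1,1,1,
  ISYM=1,
 &END
 5.2139032711554889E-01    1    1    1    1
 1.1259062334450573E-14    1    1    2    1
 4.8941513053351254E-01    1    1    2    2
 4.1298017146270116E-01    1    1    3    3
 4.1298017146270133E-01    1    1    4    4
-1.3212116986500983E-14    1    1    5    1
-1.0844028203337620E-01    1    1    5    2
 4.6924617708373323E-01    1    1    5    5
 1.0614032571579769E-01    1    1    6    1
-1.1506134409888504E-14    1    1    6    5
 4.9631644201195774E-01    1    1    6    6
 1.5626910344777781E-01    2    1    2    1
-1.2231187981939935E-14    2    1    2    2
-1.0996752304440000E-01    2    1    5    1
 5.4580453984321910E-02    2    1    6    2
-1.4280471169929082E-01    2    1    6    5
 4.7804305086592519E-01    2    2    2    2
 4.2586236793947901E-01    2    2    3    3
 4.2586236793947924E-01    2    2    4    4
-8.0155109826276050E-02    2    2    5    2
 4.4819923672953976E-01    2    2    5    5
 7.8712537690611900E-02    2    2    6    1
 1.0265051123175307E-14    2    2    6    5
 4.6171374938321580E-01    2    2    6    6
 2.0564192929800940E-02    3    1    3    1
-1.0700896170160415E-02    3    1    6    3
 6.6150661825029128E-02    3    2    3    2
 4.0623620961465455E-02    3    2    5    3
 4.4985904108667069E-01    3    3    3    3
 4.0136028264432855E-01    3    3    4    4
-2.3478529982899104E-02    3    3    5    2
 3.9243759341221268E-01    3    3    5    5
 2.7564207952449966E-02    3    3    6    1
 3.8276845135624177E-01    3    3    6    6
 2.0564192929800950E-02    4    1    4    1
-1.0700896170160425E-02    4    1    6    4
 6.6150661825029142E-02    4    2    4    2
 4.0623620961465427E-02    4    2    5    4
 2.4249379221171152E-02    4    3    4    3
 4.4985904108667107E-01    4    4    4    4
-2.3478529982899038E-02    4    4    5    2
 3.9243759341221163E-01    4    4    5    5
 2.7564207952449730E-02    4    4    6    1
 3.8276845135624094E-01    4    4    6    6
 1.0052022819513426E-01    5    1    5    1
-6.6001671272690132E-02    5    1    6    2
 1.1786965865016340E-01    5    1    6    5
 7.1195953784919094E-02    5    2    5    2
-8.8409838449358555E-02    5    2    5    5
-6.9626212372484911E-02    5    2    6    1
-1.1550757646647179E-01    5    2    6    6
 3.6873587691667022E-02    5    3    5    3
 3.6873587691667056E-02    5    4    5    4
 4.4992537867837878E-01    5    5    5    5
 1.0153686594756733E-01    5    5    6    1
 4.7018368660990573E-01    5    5    6    6
 8.0589665206525024E-02    6    1    6    1
 1.2777900474113130E-01    6    1    6    6
 5.3292594888802877E-02    6    2    6    2
-7.3384351775217821E-02    6    2    6    5
 1.0318138866658569E-02    6    3    6    3
 1.0318138866658576E-02    6    4    6    4
 1.5898875693487585E-01    6    5    6    5
 5.1139109218720258E-01    6    6    6    6
-1.8936251938940305E+00    1    1    0    0
-1.8299691093388206E+00    2    2    0    0
-1.4321281173590963E+00    3    3    0    0
-1.4321281173590972E+00    4    4    0    0
 1.8706815088772150E-01    5    2    0    0
-9.7675904006757641E-01    5    5    0    0
-2.0898494585215349E-01    6    1    0    0
 1.2192657427652922E-14    6    2    0    0
 4.7824261763113600E-02    6    6    0    0
-1.0038805572377782E+01    0    0    0    0
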