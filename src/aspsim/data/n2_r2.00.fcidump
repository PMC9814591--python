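&FCI NORB=6,NELEC=6,MS2=0,
  ORBSYM=1,1,1,1,1,1,
  ISYM=1,
 &END
 5.1082678506135148E-01    1    1    1    1
 4.6666655070535140E-01    1    1    2    2
 4.6666655070535118E-01    1    1    3    3
 4.6335378866591292E-01    1    1    4    4
 4.6335378866591342E-01    1    1    5    5
 5.2451474133361453E-01    1    1    6    6
 2.1619533957219540E-02    2    1    2    1
-1.7341298115049197E-02    2    1    6    4
 4.5798406231477104E-05    2    1    6    5
 5.1283675021963671E-01    2    2    2    2
 4.6980568745971435E-01    2    2    3    3
 5.0724282884325911E-01    2    2    4    4
-1.1010550086428191E-04    2    2    5    4
 4.6555231701025240E-01    2    2    5    5
 4.9098331741777679E-01    2    2    6    6
 2.1619533957219529E-02    3    1    3    1
-4.5798406231471616E-05    3    1    6    4
-1.7341298115049201E-02    3    1    6    5
 2.1515531379960966E-02    3    2    3    2
 1.1010550086409789E-04    3    2    4    4
 2.0845255916503474E-02    3    2    5    4
-1.1010550086427058E-04    3    2    5    5
 5.1283675021963626E-01    3    3    3    3
 4.6555231701025185E-01    3    3    4    4
 1.1010550086414456E-04    3    3    5    4
 5.0724282884325933E-01    3    3    5    5
 4.9098331741777657E-01    3    3    6    6
 2.2360068470966016E-02    4    1    4    1
-1.9230354210721959E-02    4    1    6    2
-5.0787407509788318E-05    4    1    6    3
 2.5588270302978311E-01    4    2    4    2
 6.2219375927906643E-04    4    2    4    3
-6.2219375927919653E-04    4    2    5    2
 2.1529733805940163E-01    4    2    5    3
-2.0146287455693418E-01    4    2    6    1
 2.0294325700269070E-02    4    3    4    3
 2.0291039270112231E-02    4    3    5    2
 6.2219375927911619E-04    4    3    5    3
-5.3206389212069962E-04    4    3    6    1
 5.0245253488780939E-01    4    4    4    4
 4.6186898660623832E-01    4    4    5    5
 4.8825093332801850E-01    4    4    6    6
 2.2360068470966037E-02    5    1    5    1
 5.0787407509794227E-05    5    1    6    2
-1.9230354210721962E-02    5    1    6    3
 2.0294325700269098E-02    5    2    5    2
-6.2219375927915371E-04    5    2    5    3
 5.3206389212076413E-04    5    2    6    1
 2.5588270302978322E-01    5    3    5    3
-2.0146287455693423E-01    5    3    6    1
 2.0291774140785694E-02    5    4    5    4
 5.0245253488781039E-01    5    5    5    5
 4.8825093332801900E-01    5    5    6    6
 2.2668316613212125E-01    6    1    6    1
 2.4421061745950753E-02    6    2    6    2
 2.4421061745950746E-02    6    3    6    3
 2.2518723185540181E-02    6    4    6    4
 2.2518723185540206E-02    6    5    6    5
 5.6270751249223783E-01    6    6    6    6
-2.6324327698523371E+00    1    1    0    0
-2.5034270621434898E+00    2    2    0    0
-2.5034270621434884E+00    3    3    0    0
-2.5460203491869691E+00    4    4    0    0
-2.5460203491869713E+00    5    5    0    0
-2.5081670336367123E+00    6    6    0    0
-9.8361706765366336E+01    0    0    0    0
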