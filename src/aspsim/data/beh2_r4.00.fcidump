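&FCI NORB=6,NELEC=4,MS2=0,
  ORBSYM=1,1,1,1,1,1,
  ISYM=1,
 &END
 3.9613378188808640E-01    1    1    1    1
 1.3811160975848746E-01    1    1    2    2
 3.2158754185812287E-02    1    1    3    1
 1.4017160927954139E-01    1    1    3    3
 4.0539363013043417E-01    1    1    4    4
 4.0539363013043406E-01    1    1    5    5
 2.2687804224508296E-02    1    1    6    2
 4.0377075067458951E-01    1    1    6    6
 5.9262524643866809E-03    2    1    2    1
-4.2702692378943891E-02    2    1    3    2
 9.3981905932158955E-03    2    1    6    1
 5.1566474166010378E-03    2    1    6    3
 4.1538951352818149E-01    2    2    2    2
-3.2820920499407359E-02    2    2    3    1
 4.1404188394576380E-01    2    2    3    3
 1.3158437300980980E-01    2    2    4    4
 1.3158437300980974E-01    2    2    5    5
-2.6539929562607322E-02    2    2    6    2
 1.4230840461507693E-01    2    2    6    6
 7.9090367880446395E-03    3    1    3    1
-3.2394947621040664E-02    3    1    3    3
 3.4196496639915315E-02    3    1    4    4
 3.4196496639915315E-02    3    1    5    5
 5.9281736899859981E-03    3    1    6    2
 3.2469507225701418E-02    3    1    6    6
 3.4594615031545306E-01    3    2    3    2
-1.6915513950064780E-02    3    2    6    1
-3.5088611668782195E-02    3    2    6    3
 4.1272455779856498E-01    3    3    3    3
 1.3389853475976654E-01    3    3    4    4
 1.3389853475976651E-01    3    3    5    5
-2.6271960958495356E-02    3    3    6    2
 1.4410805217724604E-01    3    3    6    6
 8.5463925361239673E-02    4    1    4    1
 1.0785863628868499E-02    4    1    4    3
 1.6102488955719031E-04    4    2    4    2
 1.9615332188901002E-03    4    2    6    4
 1.3627281908859742E-03    4    3    4    3
 4.4985904108667107E-01    4    4    4    4
 4.0136028264432877E-01    4    4    5    5
 2.2834529565307099E-02    4    4    6    2
 3.9955769117151507E-01    4    4    6    6
 8.5463925361239659E-02    5    1    5    1
 1.0785863628868497E-02    5    1    5    3
 1.6102488955719031E-04    5    2    5    2
 1.9615332188900997E-03    5    2    6    5
 1.3627281908859740E-03    5    3    5    3
 2.4249379221171180E-02    5    4    5    4
 4.4985904108667102E-01    5    5    5    5
 2.2834529565307099E-02    5    5    6    2
 3.9955769117151502E-01    5    5    6    6
 8.4616668811402687E-02    6    1    6    1
 1.1531419182006970E-02    6    1    6    3
 4.8522294622980111E-03    6    2    6    2
 2.5955533669086955E-02    6    2    6    6
 4.7644737109198785E-03    6    3    6    3
 2.4104921619343356E-02    6    4    6    4
 2.4104921619343352E-02    6    5    6    5
 4.4569409845578445E-01    6    6    6    6
-9.2227092738100580E-01    1    1    0    0
-7.9889056892956745E-01    2    2    0    0
-9.2196055196543409E-03    3    1    0    0
-7.9763677968235014E-01    3    3    0    0
-7.7062174827286611E-01    4    4    0    0
-7.7062174827286600E-01    5    5    0    0
-9.4374882848280439E-03    6    2    0    0
-7.8426474647079603E-01    6    6    0    0
-1.2844343618721352E+01    0    0    0    0
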