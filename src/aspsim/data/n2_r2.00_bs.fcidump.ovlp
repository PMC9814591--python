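-7.3916828568703685E-02  9.1690280791616646E-02  4.8493801666869415E-16 -9.2005372073423094E-15  5.8457049091601529E-02  9.9131829816371297E-01
 9.1690280791616743E-02  7.3916828568703921E-02  5.2222890715509503E-16  2.7324000436087290E-15  9.9131829816371364E-01 -5.8457049091601487E-02
-9.1773665577184309E-17 -4.5910267467467910E-17  6.6433554418249918E-01  7.4741250304282403E-01 -1.9156444454035214E-15  6.7757537959786685E-15
-4.9782454759916942E-16  5.6798165979135488E-16  7.4741250304282436E-01 -6.6435399388213812E-01  9.4849345998220105E-16 -6.6705801756078532E-15
 5.5309849500695951E-01  8.2474920411221719E-01 -1.6800029020142685E-16  2.2505934200362256E-16 -1.1432351065657810E-01 -2.8300884234525519E-02
 8.2474920411221719E-01 -5.5309849500695973E-01  5.9746174957094203E-16 -1.5886953631739124E-15 -2.8300884234525713E-02  1.1432351065657788E-01
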