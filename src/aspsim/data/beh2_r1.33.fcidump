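&FCI NORB=6,NELEC=4,MS2=0,
  ORBSYM=1,1,1,1,1,1,
  ISYM=1,
 &END
 3.9903170039986696E-01    1    1    1    1
 4.1238615975720339E-01    1    1    2    2
 3.6954917804728776E-01    1    1    3    3
 3.6954917804728776E-01    1    1    4    4
-2.4899491830140993E-02    1    1    5    1
 3.9737708452995335E-01    1    1    5    5
-5.9977916573868088E-03    1    1    6    2
 4.2879207665194569E-01    1    1    6    6
 1.6451931497690420E-01    2    1    2    1
-9.4795754751197600E-02    2    1    5    2
-4.4418837932562676E-02    2    1    6    1
 1.4287756159677337E-01    2    1    6    5
 4.3554296978242907E-01    2    2    2    2
 3.5699184506211301E-01    2    2    3    3
 3.5699184506211301E-01    2    2    4    4
-4.7845267432150868E-02    2    2    5    1
 4.0840879353883780E-01    2    2    5    5
-2.1219925975943670E-02    2    2    6    2
 4.4760179102302833E-01    2    2    6    6
 4.9486196116765503E-02    3    1    3    1
 4.7437760419607039E-02    3    1    5    3
 1.4704682560675130E-02    3    2    3    2
 1.3776379050330334E-02    3    2    6    3
 4.4985904108667069E-01    3    3    3    3
 4.0136028264432838E-01    3    3    4    4
 5.1955992451665232E-02    3    3    5    1
 3.6765306563170602E-01    3    3    5    5
 5.8999251136395571E-02    3    3    6    2
 3.9141412887869487E-01    3    3    6    6
 4.9486196116765517E-02    4    1    4    1
 4.7437760419607046E-02    4    1    5    4
 1.4704682560675131E-02    4    2    4    2
 1.3776379050330337E-02    4    2    6    4
 2.4249379221171138E-02    4    3    4    3
 4.4985904108667080E-01    4    4    4    4
 5.1955992451665226E-02    4    4    5    1
 3.6765306563170619E-01    4    4    5    5
 5.8999251136395606E-02    4    4    6    2
 3.9141412887869498E-01    4    4    6    6
 7.7614880825434482E-02    5    1    5    1
-3.5094989113362916E-02    5    1    5    5
 7.2929479391577054E-02    5    1    6    2
-3.7054187670325443E-02    5    1    6    6
 8.3430205030402854E-02    5    2    5    2
 6.1205137785538558E-02    5    2    6    1
-9.5499159662282992E-02    5    2    6    5
 5.0923122228331293E-02    5    3    5    3
 5.0923122228331300E-02    5    4    5    4
 4.1211991695326139E-01    5    5    5    5
-2.6563729744219746E-02    5    5    6    2
 4.3649838730104668E-01    5    5    6    6
 5.6584562106401809E-02    6    1    6    1
-5.5911460039849557E-02    6    1    6    5
 8.2335797436138600E-02    6    2    6    2
-1.1427740198766738E-02    6    2    6    6
 1.6531548536476627E-02    6    3    6    3
 1.6531548536476631E-02    6    4    6    4
 1.4081677282854024E-01    6    5    6    5
 4.8965247359144237E-01    6    6    6    6
-1.5176842667662467E+00    1    1    0    0
-1.5182347916405221E+00    2    2    0    0
-1.1771629789598450E+00    3    3    0    0
-1.1771629789598452E+00    4    4    0    0
 2.5794272153818739E-02    5    1    0    0
-9.8677411281963956E-01    5    5    0    0
-1.1203328759964460E-02    6    2    0    0
-6.6295140442928679E-01    6    6    0    0
-1.1643577498428670E+01    0    0    0    0
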