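&FCI NORB=6,NELEC=4,MS2=0,
  ORBSYM=1,1,1,1,1,1,
  ISYM=1,
 &END
 3.2103330592741874E-01    1    1    1    1
 2.5234273751520486E-01    1    1    2    2
 5.0668013862005257E-02    1    1    3    1
 2.6208834512405582E-01    1    1    3    3
 3.5183082016509476E-01    1    1    4    4
 3.5183082016509498E-01    1    1    5    5
-4.5525572265708247E-02    1    1    6    2
 3.3958846479785287E-01    1    1    6    6
 8.7703718230936381E-02    2    1    2    1
-1.1950604048884846E-01    2    1    3    2
-6.3656573746681483E-03    2    1    6    1
-8.1095931927601020E-02    2    1    6    3
 3.5592480792111852E-01    2    2    2    2
-7.1329990286896253E-02    2    2    3    1
 3.4812446919309259E-01    2    2    3    3
 2.0771406407044171E-01    2    2    4    4
 2.0771406407044182E-01    2    2    5    5
 6.2020005327721055E-02    2    2    6    2
 2.6190738489902093E-01    2    2    6    6
 8.6706741632675582E-02    3    1    3    1
-5.9240621732448540E-02    3    1    3    3
 1.0326102129799623E-01    3    1    4    4
 1.0326102129799630E-01    3    1    5    5
-7.7463571328287878E-02    3    1    6    2
 5.9765424109940575E-02    3    1    6    6
 2.0943666788460411E-01    3    2    3    2
-4.3427886424234313E-02    3    2    6    1
 1.0709928017163421E-01    3    2    6    3
 3.4461289184306848E-01    3    3    3    3
 2.2859932576588049E-01    3    3    4    4
 2.2859932576588066E-01    3    3    5    5
 5.4968627240412432E-02    3    3    6    2
 2.6856354792933951E-01    3    3    6    6
 6.5196521145417574E-02    4    1    4    1
 3.7873262761769375E-02    4    1    4    3
 3.8584855550700308E-03    4    2    4    2
-8.8814619444290057E-03    4    2    6    4
 2.2066088948830033E-02    4    3    4    3
 4.4985904108667013E-01    4    4    4    4
 4.0136028264432821E-01    4    4    5    5
-8.6142691978488825E-02    4    4    6    2
 3.6568311352726174E-01    4    4    6    6
 6.5196521145417644E-02    5    1    5    1
 3.7873262761769402E-02    5    1    5    3
 3.8584855550700334E-03    5    2    5    2
-8.8814619444290126E-03    5    2    6    5
 2.2066088948830050E-02    5    3    5    3
 2.4249379221171121E-02    5    4    5    4
 4.4985904108667085E-01    5    5    5    5
-8.6142691978488881E-02    5    5    6    2
 3.6568311352726196E-01    5    5    6    6
 5.9221681984899591E-02    6    1    6    1
 1.0664879505840066E-02    6    1    6    3
 7.5503856542306874E-02    6    2    6    2
-6.3806075328363257E-02    6    2    6    6
 7.7133824750809418E-02    6    3    6    3
 2.0705277606220644E-02    6    4    6    4
 2.0705277606220662E-02    6    5    6    5
 3.8312374685610034E-01    6    6    6    6
-1.0098187903836124E+00    1    1    0    0
-9.3480032249060185E-01    2    2    0    0
-2.7514073777106574E-02    3    1    0    0
-9.0351201340763998E-01    3    3    0    0
-8.5164687942415418E-01    4    4    0    0
-8.5164687942415485E-01    5    5    0    0
 2.2665481829879690E-02    6    2    0    0
-8.4878408828622820E-01    6    6    0    0
-1.2645893407716349E+01    0    0    0    0
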