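&FCI NORB=6,NELEC=6,MS2=0,
  ORBSYM=1,1,1,1,1,1,
  ISYM=1,
 &END
 6.0528144515858628E-01    1    1    1    1
 5.5449498254021579E-01    1    1    2    2
 5.2581761815626482E-01    1    1    3    3
 5.9884317305388568E-01    1    1    4    4
-8.4158108476890137E-03    1    1    5    4
 5.5516537870861715E-01    1    1    5    5
 6.3652256521967365E-01    1    1    6    6
 2.5393231309184878E-02    2    1    2    1
 8.4158108476889617E-03    2    1    4    4
 2.1838897172633917E-02    2    1    5    4
-8.4158108476889253E-03    2    1    5    5
 6.0528144515858540E-01    2    2    2    2
 5.2581761815626438E-01    2    2    3    3
 5.5516537870861715E-01    2    2    4    4
 8.4158108476888021E-03    2    2    5    4
 5.9884317305388490E-01    2    2    5    5
 6.3652256521967288E-01    2    2    6    6
 2.8395705844987826E-02    3    1    3    1
-3.0956009246871441E-03    3    1    6    4
 5.7582063895706662E-04    3    1    6    5
 2.8395705844987799E-02    3    2    3    2
-5.7582063895706553E-04    3    2    6    4
-3.0956009246871463E-03    3    2    6    5
 5.9460155716852725E-01    3    3    3    3
 5.5220306007115605E-01    3    3    4    4
 5.5220306007115572E-01    3    3    5    5
 6.0452121338524778E-01    3    3    6    6
 1.7316553026356751E-01    4    1    4    1
 2.8732003946205235E-02    4    1    4    2
-2.8732003946205249E-02    4    1    5    1
 1.3575989535188865E-01    4    1    5    2
 7.9732918594432961E-02    4    1    6    3
 2.4047330935881274E-02    4    2    4    2
 1.3358303975797349E-02    4    2    5    1
 2.8732003946205197E-02    4    2    5    2
 1.4831323949031980E-02    4    2    6    3
 4.0944574620755257E-02    4    3    4    3
-7.5372421251606505E-03    4    3    6    1
-1.4020216694833622E-03    4    3    6    2
 6.1920484223382233E-01    4    4    4    4
 5.6775858810424418E-01    4    4    5    5
 6.3754080537281355E-01    4    4    6    6
 2.4047330935881284E-02    5    1    5    1
-2.8732003946205238E-02    5    1    5    2
-1.4831323949031989E-02    5    1    6    3
 1.7316553026356724E-01    5    2    5    2
 7.9732918594432906E-02    5    2    6    3
 4.0944574620755236E-02    5    3    5    3
 1.4020216694833616E-03    5    3    6    1
-7.5372421251606366E-03    5    3    6    2
 2.5723127064788805E-02    5    4    5    4
 6.1920484223382133E-01    5    5    5    5
 6.3754080537281332E-01    5    5    6    6
 3.6745101131738088E-02    6    1    6    1
 3.6745101131738053E-02    6    2    6    2
 8.2888874909275184E-02    6    3    6    3
 5.0586007269682751E-02    6    4    6    4
 5.0586007269682723E-02    6    5    6    5
 7.7282773021871798E-01    6    6    6    6
-3.3582317470803011E+00    1    1    0    0
-3.3582317470802980E+00    2    2    0    0
-3.2060448115698317E+00    3    3    0    0
-2.8449049112801332E+00    4    4    0    0
-2.8449049112801319E+00    5    5    0    0
-2.2132084478584191E+00    6    6    0    0
-9.5639831877164369E+01    0    0    0    0
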