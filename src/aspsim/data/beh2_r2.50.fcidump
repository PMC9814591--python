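&FCI NORB=6,NELEC=4,MS2=0,
  ORBSYM=1,1,1,1,1,1,
  ISYM=1,
 &END
 3.1488741530116687E-01    1    1    1    1
 3.0346124288547516E-01    1    1    2    2
 2.0538376383286799E-02    1    1    3    1
 3.0860048803673895E-01    1    1    3    3
 3.3019680555535280E-01    1    1    4    4
 3.3019680555535280E-01    1    1    5    5
-2.3346238282530685E-02    1    1    6    2
 3.3454351205887234E-01    1    1    6    6
 1.2460734414905510E-01    2    1    2    1
-1.0757659368539249E-01    2    1    3    2
 1.7924021977756957E-02    2    1    6    1
-1.1532582679946397E-01    2    1    6    3
 3.4539550742864317E-01    2    2    2    2
-5.1663671613786620E-02    2    2    3    1
 3.3625177784655874E-01    2    2    3    3
 2.5621537097225061E-01    2    2    4    4
 2.5621537097225067E-01    2    2    5    5
 4.0184208704930897E-02    2    2    6    2
 3.2147230625565215E-01    2    2    6    6
 1.0126774147513262E-01    3    1    3    1
-3.6100303577704038E-02    3    1    3    3
 1.0346895347632545E-01    3    1    4    4
 1.0346895347632547E-01    3    1    5    5
-9.4750791119788916E-02    3    1    6    2
 2.9926052223446631E-02    3    1    6    6
 1.3845206358851714E-01    3    2    3    2
-6.5404052511192023E-02    3    2    6    1
 9.9491297198344916E-02    3    2    6    3
 3.3842699342487109E-01    3    3    3    3
 2.8214143928037716E-01    3    3    4    4
 2.8214143928037722E-01    3    3    5    5
 3.3662315996527831E-02    3    3    6    2
 3.2417776461957570E-01    3    3    6    6
 5.2834505817068375E-02    4    1    4    1
 4.3179437647493178E-02    4    1    4    3
 6.8484280327979520E-03    4    2    4    2
-1.1035519563081230E-02    4    2    6    4
 3.5628871090539117E-02    4    3    4    3
 4.4985904108667052E-01    4    4    4    4
 4.0136028264432827E-01    4    4    5    5
-9.2772488947830814E-02    4    4    6    2
 3.5107371913219149E-01    4    4    6    6
 5.2834505817068382E-02    5    1    5    1
 4.3179437647493185E-02    5    1    5    3
 6.8484280327979529E-03    5    2    5    2
-1.1035519563081233E-02    5    2    6    5
 3.5628871090539124E-02    5    3    5    3
 2.4249379221171086E-02    5    4    5    4
 4.4985904108667063E-01    5    5    5    5
-9.2772488947830814E-02    5    5    6    2
 3.5107371913219160E-01    5    5    6    6
 5.7422976082054461E-02    6    1    6    1
-1.5737697737828616E-02    6    1    6    3
 9.7696062881270612E-02    6    2    6    2
-4.1343543653430362E-02    6    2    6    6
 1.1110409682454188E-01    6    3    6    3
 1.8374674805469844E-02    6    4    6    4
 1.8374674805469848E-02    6    5    6    5
 3.7493166365428482E-01    6    6    6    6
-1.0982670205065599E+00    1    1    0    0
-1.0521421384034011E+00    2    2    0    0
-2.4787626789432096E-02    3    1    0    0
-9.5651095238414596E-01    3    3    0    0
-9.1320089592764453E-01    4    4    0    0
-9.1320089592764464E-01    5    5    0    0
 2.4432287119595966E-02    6    2    0    0
-8.7129493181596984E-01    6    6    0    0
-1.2487163866367940E+01    0    0    0    0
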