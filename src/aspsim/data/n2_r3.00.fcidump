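&FCI NORB=6,NELEC=6,MS2=0,
  ORBSYM=1,1,1,1,1,1,
  ISYM=1,
 &END
 4.6809735667761204E-01    1    1    1    1
 4.2677861439536274E-01    1    1    2    2
 4.3108395708190067E-01    1    1    3    3
 4.2160929966064256E-11    1    1    4    3
 4.2807243873797707E-01    1    1    4    4
 4.8727663356258991E-11    1    1    5    1
-2.9303434823329995E-12    1    1    5    2
 4.6734781130717795E-01    1    1    5    5
-3.4031147701562734E-12    1    1    6    1
-4.1958428607648119E-11    1    1    6    2
-2.8632965625875377E-03    1    1    6    5
 4.2654915150660133E-01    1    1    6    6
 2.0659371141124663E-02    2    1    2    1
-2.3639279812850484E-13    2    1    5    1
 3.3844431878420920E-12    2    1    5    2
-2.8632965625875065E-03    2    1    5    5
-3.3845755714262328E-12    2    1    6    1
-2.3634791075150523E-13    2    1    6    2
-2.0399329900288220E-02    2    1    6    5
 2.8632965625875820E-03    2    1    6    6
 4.6809735667761232E-01    2    2    2    2
 4.3108395708190078E-01    2    2    3    3
 4.2159309615784004E-11    2    2    4    3
 4.2807243873797718E-01    2    2    4    4
 4.1956841760169078E-11    2    2    5    1
-3.4029668256498406E-12    2    2    5    2
 4.2654915150660150E-01    2    2    5    5
-2.9302359527033013E-12    2    2    6    1
-4.8725596160823815E-11    2    2    6    2
 2.8632965625874666E-03    2    2    6    5
 4.6734781130717801E-01    2    2    6    6
 2.0950098477599034E-02    3    1    3    1
 3.5502691022186877E-12    3    1    4    1
-7.5354010882758136E-12    3    1    5    3
 2.0667630910618184E-02    3    1    5    4
 5.2626197790466608E-13    3    1    6    3
-1.4434033000595540E-03    3    1    6    4
 2.0950098477599037E-02    3    2    3    2
 3.5501328682515273E-12    3    2    4    2
 5.2626348151390637E-13    3    2    5    3
-1.4434033000595510E-03    3    2    5    4
 7.5353998511312982E-12    3    2    6    3
-2.0667630910618184E-02    3    2    6    4
 4.7751677133324361E-01    3    3    3    3
-1.0510072692531826E-10    3    3    4    3
 4.7415421544557373E-01    3    3    4    4
-9.1811177397594629E-11    3    3    5    1
 6.4119781966224455E-12    3    3    5    2
 4.3071821522568704E-01    3    3    5    5
 6.4119548079108463E-12    3    3    6    1
 9.1811241259376688E-11    3    3    6    2
 4.3071821522568693E-01    3    3    6    6
 2.0154797798056394E-02    4    1    4    1
 2.0353500642596285E-02    4    1    5    3
 7.5396233290733528E-12    4    1    5    4
-1.4214648075699065E-03    4    1    6    3
-5.2656018295721479E-13    4    1    6    4
 2.0154797798056401E-02    4    2    4    2
-1.4214648075699038E-03    4    2    5    3
-5.2655883958582353E-13    4    2    5    4
-2.0353500642596289E-02    4    2    6    3
-7.5396203779648386E-12    4    2    6    4
 2.8869180656317533E-01    4    3    4    3
 1.0626447318101635E-10    4    3    4    4
 2.5061521844617096E-01    4    3    5    1
-1.7502675314590686E-02    4    3    5    2
-4.1046210387181492E-11    4    3    5    5
-1.7502675314590720E-02    4    3    6    1
-2.5061521844617091E-01    4    3    6    2
-4.1044584027041547E-11    4    3    6    6
 4.7116944447353309E-01    4    4    4    4
 9.1737184924206095E-11    4    4    5    1
-6.4068323997894856E-12    4    4    5    2
 4.2773927803019512E-01    4    4    5    5
-6.4068518057071413E-12    4    4    6    1
-9.1737115199387654E-11    4    4    6    2
 4.2773927803019512E-01    4    4    6    6
 2.9392422886841801E-01    5    1    5    1
-1.9094284151378395E-02    5    1    5    2
-4.8818331855393642E-11    5    1    5    5
-1.9094284151378399E-02    5    1    6    1
-2.5288568534872863E-01    5    1    6    2
 2.3715775077796628E-13    5    1    6    5
-4.2027724898498852E-11    5    1    6    6
 2.1852794352519470E-02    5    2    5    2
 3.4094119207741031E-12    5    2    5    5
-1.9185749167169773E-02    5    2    6    1
 1.9094284151378361E-02    5    2    6    2
 3.3944669653911328E-12    5    2    6    5
 2.9351489104315148E-12    5    2    6    6
 2.0655088212202879E-02    5    3    5    3
-3.3763959286090412E-12    5    3    5    4
 2.0500312211755620E-02    5    4    5    4
 4.6700253372090189E-01    5    5    5    5
 2.9352570558612347E-12    5    5    6    1
 4.2029421253788936E-11    5    5    6    2
 4.2592301633521573E-01    5    5    6    6
 2.1852794352519470E-02    6    1    6    1
 1.9094284151378444E-02    6    1    6    2
-3.3943452830974205E-12    6    1    6    5
 3.4092468147781592E-12    6    1    6    6
 2.9392422886841807E-01    6    2    6    2
 2.3696294243333654E-13    6    2    6    5
 4.8816484054337370E-11    6    2    6    6
 2.0655088212202868E-02    6    3    6    3
-3.3762611935081980E-12    6    3    6    4
 2.0500312211755616E-02    6    4    6    4
 2.0539758692842920E-02    6    5    6    5
 4.6700253372090172E-01    6    6    6    6
-2.2765516739996143E+00    1    1    0    0
-2.2765516739996152E+00    2    2    0    0
-2.2871276205429623E+00    3    3    0    0
 3.5942033619509133E-12    4    3    0    0
-2.3068326375357149E+00    4    4    0    0
-1.6366911703038455E-13    5    1    0    0
 1.1467480627063804E-14    5    2    0    0
-2.2789141894190936E+00    5    5    0    0
 1.1636476492076085E-14    6    1    0    0
 1.6348619644313919E-13    6    2    0    0
-2.2789141894190927E+00    6    6    0    0
-9.9155897766107074E+01    0    0    0    0
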