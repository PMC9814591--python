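beh2_r0.70:
  atoms:
  - - Be
    - - 0.0
      - 0.0
      - 0.0
  - - H
    - - 0.0
      - 0.0
      - 1.3228082872380391
  - - H
    - - 0.0
      - 0.0
      - -1.3228082872380391
  basis: STO-3G
  bs_fcidump: null
  bs_pairs:
  - - 1
    - 4
  delta_eps: 0.6882069504233773
  e_bs_uhf: -14.841438485623513
  e_rhf: -14.841438485623506
  fcidump: beh2_r0.70.fcidump
  mo_energies:
  - -4.68466541744171
  - -0.5496736993566722
  - -0.5293648489159535
  - 0.15884210150742387
  - 0.15884210150742414
  - 0.6864155513767641
  - 1.830002367173208
  n_elec_active: 4
  n_luno:
  - 3.1321698985284484e-15
  n_orb_active: 6
  units: bohr
  y:
  - 0.0
beh2_r1.33:
  atoms:
  - - Be
    - - 0.0
      - 0.0
      - 0.0
  - - H
    - - 0.0
      - 0.0
      - 2.5057768412537715
  - - H
    - - 0.0
      - 0.0
      - -2.5057768412537715
  basis: STO-3G
  bs_fcidump: null
  bs_pairs:
  - - 1
    - 4
  delta_eps: 0.6341670025326701
  e_bs_uhf: -15.560334935984915
  e_rhf: -15.560334935984912
  fcidump: beh2_r1.33.fcidump
  mo_energies:
  - -4.5194441472662055
  - -0.4583995591457806
  - -0.4224388133010691
  - 0.21172818923160105
  - 0.21172818923160117
  - 0.46375255620576233
  - 0.950915967896608
  n_elec_active: 4
  n_luno:
  - 4.1259855330043276e-16
  n_orb_active: 6
  units: bohr
  y:
  - 0.0
beh2_r2.00:
  atoms:
  - - Be
    - - 0.0
      - 0.0
      - 0.0
  - - H
    - - 0.0
      - 0.0
      - 3.7794522492515403
  - - H
    - - 0.0
      - 0.0
      - -3.7794522492515403
  basis: STO-3G
  bs_fcidump: beh2_r2.00_bs.fcidump
  bs_pairs:
  - - 1
    - 2
  delta_eps: 0.5053197675847045
  e_bs_uhf: -15.365429639310172
  e_rhf: -15.354417332545026
  fcidump: beh2_r2.00.fcidump
  mo_energies:
  - -4.556159828588472
  - -0.35447118964515767
  - -0.29994524657663635
  - 0.20537452100806813
  - 0.20778078653630702
  - 0.20778078653630713
  - 0.4405503590588938
  n_elec_active: 4
  n_luno:
  - 0.27341977510822574
  n_orb_active: 6
  units: bohr
  y:
  - 0.04892823642520305
beh2_r2.50:
  atoms:
  - - Be
    - - 0.0
      - 0.0
      - 0.0
  - - H
    - - 0.0
      - 0.0
      - 4.724315311564426
  - - H
    - - 0.0
      - 0.0
      - -4.724315311564426
  basis: STO-3G
  bs_fcidump: beh2_r2.50_bs.fcidump
  bs_pairs:
  - - 1
    - 2
  delta_eps: 0.3179052684340654
  e_bs_uhf: -15.301975484453184
  e_rhf: -15.16306897821427
  fcidump: beh2_r2.50.fcidump
  mo_energies:
  - -4.561502963435878
  - -0.3010644637618301
  - -0.2244314949303336
  - 0.09347377350373184
  - 0.19994052193460143
  - 0.1999405219346015
  - 0.28561767046877984
  n_elec_active: 4
  n_luno:
  - 0.8085296634916496
  n_orb_active: 6
  units: bohr
  y:
  - 0.6306017938957953
beh2_r3.00:
  atoms:
  - - Be
    - - 0.0
      - 0.0
      - 0.0
  - - H
    - - 0.0
      - 0.0
      - 5.66917837387731
  - - H
    - - 0.0
      - 0.0
      - -5.66917837387731
  basis: STO-3G
  bs_fcidump: beh2_r3.00_bs.fcidump
  bs_pairs:
  - - 1
    - 2
  delta_eps: 0.1826639634761738
  e_bs_uhf: -15.289575421497329
  e_rhf: -15.024210006017299
  fcidump: beh2_r3.00.fcidump
  mo_energies:
  - -4.546003440029016
  - -0.2718037276532178
  - -0.1618937577683982
  - 0.02077020570777559
  - 0.19838788234802943
  - 0.19838788234802957
  - 0.2194820725784785
  n_elec_active: 4
  n_luno:
  - 0.9581431539511036
  n_orb_active: 6
  units: bohr
  y:
  - 0.9164327174103626
beh2_r4.00:
  atoms:
  - - Be
    - - 0.0
      - 0.0
      - 0.0
  - - H
    - - 0.0
      - 0.0
      - 7.558904498503081
  - - H
    - - 0.0
      - 0.0
      - -7.558904498503081
  basis: STO-3G
  bs_fcidump: beh2_r4.00_bs.fcidump
  bs_pairs:
  - - 1
    - 2
  delta_eps: 0.07013910798825895
  e_bs_uhf: -15.285058557038482
  e_rhf: -14.934549381821057
  fcidump: beh2_r4.00.fcidump
  mo_energies:
  - -4.49079774717884
  - -0.2558401784752132
  - -0.11320408828892571
  - -0.043064980300666765
  - 0.21770930762668558
  - 0.2177093076266857
  - 0.21842466571612032
  n_elec_active: 4
  n_luno:
  - 0.9990306603648139
  n_orb_active: 6
  units: bohr
  y:
  - 0.9980613225512467
n2_r1.00:
  atoms:
  - - N
    - - 0.0
      - 0.0
      - 0.0
  - - N
    - - 0.0
      - 0.0
      - 1.8897261246257702
  basis: STO-3G
  bs_fcidump: null
  bs_pairs:
  - - 0
    - 3
  - - 1
    - 4
  - - 2
    - 5
  delta_eps: 0.8943250700331999
  e_bs_uhf: -107.41953245172691
  e_rhf: -107.41953245172685
  fcidump: n2_r1.00.fcidump
  mo_energies:
  - -15.55930282028081
  - -15.554464181208914
  - -1.5401481395168233
  - -0.7100417789209825
  - -0.6461140376829928
  - -0.6461140376829921
  - -0.5649641934662817
  - 0.3293608765669183
  - 0.3293608765669187
  - 1.3855451626182438
  n_elec_active: 6
  n_luno:
  - 2.29266812419787e-16
  - -7.222207494755678e-18
  - -4.440892098500626e-16
  n_orb_active: 6
  units: bohr
  y:
  - 0.0
  - 0.0
  - 0.0
n2_r2.00:
  atoms:
  - - N
    - - 0.0
      - 0.0
      - 0.0
  - - N
    - - 0.0
      - 0.0
      - 3.7794522492515403
  basis: STO-3G
  bs_fcidump: n2_r2.00_bs.fcidump
  bs_pairs:
  - - 0
    - 5
  - - 1
    - 3
  - - 2
    - 4
  delta_eps: 0.18852132358176094
  e_bs_uhf: -107.29923578092763
  e_rhf: -106.62073431125145
  fcidump: n2_r2.00.fcidump
  mo_energies:
  - -15.329197061174968
  - -15.328536609828674
  - -0.9382757144011941
  - -0.8283608699102998
  - -0.2981788498840151
  - -0.1607809009308972
  - -0.16078090093089573
  - 0.02774042265086521
  - 0.027740422650866743
  - 0.2292704290776063
  n_elec_active: 6
  n_luno:
  - 0.8822256176594868
  - 0.8822256176594834
  - 0.33564600431189695
  n_orb_active: 6
  units: bohr
  y:
  - 0.7676737869481287
  - 0.7676737869481222
  - 0.07816073232582976
n2_r3.00:
  atoms:
  - - N
    - - 0.0
      - 0.0
      - 0.0
  - - N
    - - 0.0
      - 0.0
      - 5.66917837387731
  basis: STO-3G
  bs_fcidump: n2_r3.00_bs.fcidump
  bs_pairs:
  - - 0
    - 4
  - - 1
    - 5
  - - 2
    - 3
  delta_eps: 0.15193905185709813
  e_bs_uhf: -107.43814209484117
  e_rhf: -106.39198124045893
  fcidump: n2_r3.00.fcidump
  mo_energies:
  - -15.301987272665716
  - -15.301811302572187
  - -0.860387455396681
  - -0.8575288219228435
  - -0.13433857336155106
  - -0.13433857336155056
  - -0.127175469154305
  - 0.024763582702793125
  - 0.033884130539995595
  - 0.03388413053999615
  n_elec_active: 6
  n_luno:
  - 0.9933550763105294
  - 0.9933550763105281
  - 0.9474323970237613
  n_orb_active: 6
  units: bohr
  y:
  - 0.9867107394085043
  - 0.9867107394085016
  - 0.8951545191093763
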