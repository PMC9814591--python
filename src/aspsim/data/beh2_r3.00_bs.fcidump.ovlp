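 1.0225502229685202E-02 -2.0942867748807142E-01  1.8110990201752546E-16  5.3958493896703252E-15 -4.4448901357598436E-01  8.7089871088852067E-01
-2.0942867748807154E-01  8.0027921353718323E-01  5.5702516291577728E-17  7.1266340552894012E-15 -5.5488412844243373E-01 -8.8296182552274519E-02
-3.8611677371466033E-15 -4.9023014318871444E-15  6.9389004665484810E-01  7.2008096985917658E-01  4.3453871843980470E-15 -3.4087692540122926E-15
 2.4507923711978416E-15  3.0782543215260182E-15  7.2008096985917647E-01 -6.9389004665484855E-01 -5.8581557115794136E-15  2.0683952378140486E-15
 4.4448901357598514E-01  5.5488412844243373E-01  2.0493513693183581E-15  3.0415275694227731E-15  5.6613485299368749E-01  4.1716037458359856E-01
 8.7089871088852044E-01 -8.8296182552274935E-02 -9.0168245206166433E-17  4.9595659538848167E-15 -4.1716037458359922E-01 -2.4436873762688344E-01
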