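 4.5900966845608012E-04 -3.7781164047359879E-02 -1.5233282061905273E-01  1.1259147368736504E-16  1.1328861391200665E-15 -9.8760674591436592E-01
-3.7781164047359719E-02  9.9837257160363901E-01  1.3976636594078292E-02  1.4519329002144153E-18 -5.4178195390079556E-18 -4.0366391233972440E-02
 1.5233282061905293E-01 -1.3976636594078305E-02  9.7677148843031858E-01  2.7951063262139866E-16 -2.3902288359969088E-15 -1.5005606236284327E-01
-2.5020631850805582E-16 -1.5662503038854717E-19 -7.8900900501801212E-16  9.7544814566831384E-01 -2.2022923310098269E-01 -3.7477975008252325E-17
 2.3014431423883471E-16  6.5747001477511278E-18 -2.5852182957936810E-15 -2.2022923310098258E-01 -9.7544814566831428E-01 -7.8821052293885333E-16
-9.8760674591436592E-01 -4.0366391233972308E-02  1.5005606236284319E-01 -2.7394550866239381E-16 -4.6125547939616923E-16 -2.2060091100488947E-02
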