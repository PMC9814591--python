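-5.2317522249454296E-03 -4.0968692031417174E-03  5.8557385992745645E-15 -9.9607167384375295E-01  8.8300990920229125E-02 -1.3838819546037969E-13
 4.0968692031416037E-03 -5.2317522249458771E-03  1.5515842621049848E-14  8.8300990920228972E-02  9.9607167384375306E-01 -3.4353379882270143E-13
-6.5034300787276782E-16  1.9377784996224863E-15  5.2473882743552108E-02  1.0769794015445411E-13 -3.5487031734679908E-13 -9.9733093404631235E-01
-8.0583584618287163E-01  5.9210170869380607E-01 -2.4348574009119288E-16  2.3482913718030577E-03  6.2161962842235850E-03 -2.9530048508846966E-16
 5.9210170869380574E-01  8.0583584618287141E-01  7.7751896779978149E-16 -6.2161962842233725E-03  2.3482913718031809E-03 -2.8650899905469410E-16
 6.5770540331925772E-16  4.7869107876939957E-16 -9.9733093404631257E-01  1.3013916801697228E-15 -2.7358059797839556E-15 -5.2567619490839976E-02
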