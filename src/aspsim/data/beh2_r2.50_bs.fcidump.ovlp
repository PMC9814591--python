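 4.5770489595130866E-02 -4.3224788280316451E-01  1.4201105213925825E-15  4.8939832153517522E-16 -5.5313166362474575E-01  7.1071240785361256E-01
-4.3224788280316478E-01  5.9607668867517183E-01  1.7088318138040647E-15  6.9574138627628986E-16 -6.6464095324252248E-01 -1.2691074078421069E-01
 7.4608261227244815E-16  1.0115582313283908E-15 -4.6431141323437414E-01 -8.8567201126618988E-01 -1.5840387656000469E-15  8.8885113721385770E-16
 2.2652470847059245E-15  2.5353335770736631E-15 -8.8567201126619000E-01  4.6431141323437436E-01 -1.2976070765153434E-15  1.8463610964358421E-15
-5.5313166362474608E-01 -6.6464095324252292E-01 -3.5622947037995309E-15  8.6963945718119080E-16 -1.4449084495624470E-01 -4.8105999592137627E-01
-7.1071240785361112E-01  1.2691074078421158E-01 -1.3335703890897934E-15 -9.7975094381329610E-17  4.8105999592137721E-01  4.9735492124082720E-01
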