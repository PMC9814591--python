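 2.9080740325391602E-01 -8.0911995063864961E-01 -1.0444992855348623E-16 -1.3181918333051228E-16 -3.5896538586564014E-01  3.6318004439225127E-01
-8.0911995063864917E-01 -8.3093404956177813E-02  1.4172671524324843E-16 -1.7422656076348813E-16 -5.7252597266695449E-01 -1.0312137817173944E-01
 2.4629414902093157E-17  3.0702649920712426E-16  6.8043953529865975E-01 -7.3280422952009727E-01  3.0742192465044392E-16  4.4860701436050808E-16
-2.0824479617940936E-16 -6.6158803209907545E-17  7.3280422952009749E-01  6.8043953529865986E-01  1.7981803783787801E-16  5.7922163684774887E-16
-3.5896538586563986E-01 -5.7252597266695404E-01  1.3551317320313229E-16 -1.5500635082478346E-16  6.5225246454022001E-01 -3.4340118233158767E-01
-3.6318004439225182E-01  1.0312137817173855E-01 -6.7027191956255956E-16  4.5201091374280796E-17  3.4340118233158712E-01  8.5996571070804362E-01
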