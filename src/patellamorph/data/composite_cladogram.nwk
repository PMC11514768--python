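((((Ceratotherium_simum:17,Diceros_bicornis:17):13,(Dicerorhinus_sumatrensis:26,(Rhinoceros_sondaicus:12,Rhinoceros_unicornis:12):14):4):20,(Tapirus_indicus:23,(Tapirus_bairdii:12,(Tapirus_pinchaque:5,Tapirus_terrestris:5):7):11):27):6,(Equus_ferus:4.5,((Equus_africanus:2.8,Equus_hemionus:2.8):1.2,(Equus_grevyi:2.3,(Equus_zebra:2.0,(Equus_quagga:1.5,Equus_burchellii:1.5):0.5):0.3):1.7):0.5):51.5);
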