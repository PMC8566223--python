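composition,fraction
Hex1HexNAc1NeuAc1,0.4200000000
Hex1HexNAc1NeuAc2,0.3800000000
Hex1HexNAc1,0.0500000000
Hex0HexNAc1,0.0200000000
Hex1HexNAc1Fuc1NeuAc1,0.0200000000
Hex2HexNAc2NeuAc1,0.0300000000
Hex2HexNAc2NeuAc2,0.0300000000
Hex1HexNAc2NeuAc1,0.0100000000
Hex2HexNAc2,0.0100000000
Hex2HexNAc2Fuc1NeuAc1,0.0100000000
Hex0HexNAc2,0.0050000000
Hex2HexNAc2NeuAc3,0.0050000000
Hex1HexNAc1Fuc1NeuAc2,0.0100000000
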