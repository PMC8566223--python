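composition,fraction
Hex5HexNAc4NeuAc2,0.3092783505
Hex5HexNAc4Fuc1NeuAc2,0.1082474227
Hex5HexNAc4NeuAc1,0.0927835052
Hex5HexNAc4Fuc1NeuAc1,0.0412371134
Hex6HexNAc5NeuAc3,0.0721649485
Hex6HexNAc5Fuc1NeuAc3,0.0360824742
Hex6HexNAc5NeuAc2,0.0206185567
Hex7HexNAc6NeuAc4,0.0154639175
Hex7HexNAc6Fuc1NeuAc3,0.0103092784
Hex5HexNAc4,0.0206185567
Hex5HexNAc4Fuc1,0.0206185567
Hex4HexNAc4NeuAc1,0.0154639175
Hex4HexNAc4Fuc1NeuAc1,0.0103092784
Hex4HexNAc4,0.0103092784
Hex3HexNAc4Fuc1,0.0103092784
Hex4HexNAc3NeuAc1,0.0103092784
Hex5HexNAc2,0.0206185567
Hex6HexNAc2,0.0257731959
Hex7HexNAc2,0.0154639175
Hex8HexNAc2,0.0206185567
Hex9HexNAc2,0.0412371134
Hex6HexNAc3NeuAc1,0.0309278351
Hex5HexNAc5NeuAc2,0.0154639175
Hex5HexNAc5Fuc1NeuAc2,0.0103092784
Hex3HexNAc2,0.0154639175
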