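protein,protein_name,site,peptide,composition,actual_fraction,expected
P01009,A1AT,Asn70,ADTHDEILEGLNFNLTEIPEAQIHEGFQELLR,Hex5HexNAc4NeuAc2,0.620,1
P01009,A1AT,Asn70,ADTHDEILEGLNFNLTEIPEAQIHEGFQELLR,Hex5HexNAc4Fuc1NeuAc2,0.140,1
P01009,A1AT,Asn70,ADTHDEILEGLNFNLTEIPEAQIHEGFQELLR,Hex5HexNAc4NeuAc1,0.140,1
P01009,A1AT,Asn70,ADTHDEILEGLNFNLTEIPEAQIHEGFQELLR,Hex6HexNAc5NeuAc3,0.100,1
P01009,A1AT,Asn107,YLGNATAIFFLPDEGK,Hex5HexNAc4NeuAc2,0.560,1
P01009,A1AT,Asn107,YLGNATAIFFLPDEGK,Hex6HexNAc5NeuAc3,0.240,1
P01009,A1AT,Asn107,YLGNATAIFFLPDEGK,Hex5HexNAc4Fuc1NeuAc2,0.120,1
P01009,A1AT,Asn107,YLGNATAIFFLPDEGK,Hex7HexNAc6NeuAc4,0.080,1
P01009,A1AT,Asn271,QINDYVEKGTQGKIVDLVKELDRDTVFALVNYIFFK,Hex5HexNAc4NeuAc2,0.700,1
P01009,A1AT,Asn271,QINDYVEKGTQGKIVDLVKELDRDTVFALVNYIFFK,Hex5HexNAc4NeuAc1,0.180,1
P01009,A1AT,Asn271,QINDYVEKGTQGKIVDLVKELDRDTVFALVNYIFFK,Hex6HexNAc5NeuAc3,0.120,1
P00450,CP,Asn138,EHEGAIYPDNTTDFQR,Hex5HexNAc4NeuAc2,0.540,1
P00450,CP,Asn138,EHEGAIYPDNTTDFQR,Hex5HexNAc4Fuc1NeuAc2,0.200,1
P00450,CP,Asn138,EHEGAIYPDNTTDFQR,Hex6HexNAc5NeuAc3,0.160,1
P00450,CP,Asn138,EHEGAIYPDNTTDFQR,Hex5HexNAc4NeuAc1,0.100,1
P00450,CP,Asn358,ELHHLQEQNVSNAFLDK,Hex5HexNAc4NeuAc2,0.620,1
P00450,CP,Asn358,ELHHLQEQNVSNAFLDK,Hex6HexNAc5NeuAc3,0.220,1
P00450,CP,Asn358,ELHHLQEQNVSNAFLDK,Hex6HexNAc5Fuc1NeuAc3,0.160,1
P00450,CP,Asn762,ENLTAPGSDSAVFFEQGTTR,Hex5HexNAc4NeuAc2,0.660,1
P00450,CP,Asn762,ENLTAPGSDSAVFFEQGTTR,Hex5HexNAc4Fuc1NeuAc2,0.180,1
P00450,CP,Asn762,ENLTAPGSDSAVFFEQGTTR,Hex5HexNAc4NeuAc1,0.160,1
P00738,HP,Asn184,NLFLNHSENATAK,Hex5HexNAc4NeuAc2,0.500,1
P00738,HP,Asn184,NLFLNHSENATAK,Hex5HexNAc4Fuc1NeuAc2,0.180,1
P00738,HP,Asn184,NLFLNHSENATAK,Hex6HexNAc5NeuAc3,0.180,1
P00738,HP,Asn184,NLFLNHSENATAK,Hex5HexNAc4NeuAc1,0.140,1
P00738,HP,Asn241,VVLHPNYSQVDIGLIK,Hex5HexNAc4NeuAc2,0.580,1
P00738,HP,Asn241,VVLHPNYSQVDIGLIK,Hex6HexNAc5NeuAc3,0.240,1
P00738,HP,Asn241,VVLHPNYSQVDIGLIK,Hex5HexNAc4Fuc1NeuAc2,0.180,1
P01857,IgG1,Asn180,EEQYNSTYR,Hex3HexNAc4Fuc1,0.380,1
P01857,IgG1,Asn180,EEQYNSTYR,Hex4HexNAc4Fuc1NeuAc1,0.240,1
P01857,IgG1,Asn180,EEQYNSTYR,Hex4HexNAc4Fuc1,0.200,1
P01857,IgG1,Asn180,EEQYNSTYR,Hex5HexNAc4Fuc1NeuAc1,0.120,1
P01857,IgG1,Asn180,EEQYNSTYR,Hex3HexNAc4,0.060,1
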