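well_id,carbon_source,category
A1,water,control
A2,L-alanine,amino acids
A3,L-arginine,amino acids
A4,L-aspartic acid,amino acids
A5,L-glutamic acid,amino acids
A6,L-histidine,amino acids
A7,L-serine,amino acids
A8,L-threonine,amino acids
A9,L-proline,amino acids
A10,L-phenylalanine,amino acids
A11,glycyl-L-proline,amino acids
A12,L-methionine,amino acids
B1,L-isoleucine,amino acids
B2,D-glucose,monosaccharides
B3,D-fructose,monosaccharides
B4,D-galactose,monosaccharides
B5,D-mannose,monosaccharides
B6,L-rhamnose,monosaccharides
B7,L-fucose,monosaccharides
B8,D-arabinose,monosaccharides
B9,D-xylose,monosaccharides
B10,D-ribose,monosaccharides
B11,N-acetyl-D-glucosamine,monosaccharides
B12,D-mannitol,monosaccharides
C1,D-sorbitol,monosaccharides
C2,acetic acid,carboxylic acids
C3,propionic acid,carboxylic acids
C4,citric acid,carboxylic acids
C5,L-malic acid,carboxylic acids
C6,D-malic acid,carboxylic acids
C7,fumaric acid,carboxylic acids
C8,succinic acid,carboxylic acids
C9,alpha-ketoglutaric acid,carboxylic acids
C10,L-lactic acid,carboxylic acids
C11,pyruvic acid,carboxylic acids
C12,bromosuccinic acid,carboxylic acids
D1,quinic acid,carboxylic acids
D2,D-saccharic acid,carboxylic acids
D3,gamma-aminobutyric acid,carboxylic acids
D4,methyl pyruvate,esters
D5,methyl D-lactate,esters
D6,tween 40,esters
D7,tween 80,esters
D8,D-lactic acid methyl ester,esters
D9,acetoacetic acid ester,esters
D10,alpha-hydroxybutyric acid,fatty acids
D11,beta-hydroxy-DL-butyric acid,fatty acids
D12,alpha-ketobutyric acid,fatty acids
E1,propionic fatty acid,fatty acids
E2,butyric acid,fatty acids
E3,caproic acid,fatty acids
E4,D-gluconic acid,hexonic acid
E5,D-galactonic acid lactone,hexonic acid
E6,D-glucuronic acid,hexonic acid
E7,glucuronamide,hexonic acid
E8,mucic acid,hexonic acid
E9,D-glucose-6-phosphate,hexosephosphate
E10,D-fructose-6-phosphate,hexosephosphate
E11,D-glucose-1-phosphate,hexosephosphate
E12,DL-alpha-glycerol phosphate,hexosephosphate
F1,sucrose,other
F2,D-turanose,other
F3,stachyose,other
F4,D-raffinose,other
F5,alpha-D-lactose,other
F6,D-melibiose,other
F7,beta-methyl-D-glucoside,other
F8,D-salicin,other
F9,D-cellobiose,other
F10,gentiobiose,other
F11,D-maltose,other
F12,D-trehalose,other
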