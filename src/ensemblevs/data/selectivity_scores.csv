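compound_id,kind,native_receptor,original_conformation,original_score,dor_cc,kor_cc,mor_cc
DPI-287,crystal_ligand,dor,,,-8.6,-5.4,-3.9
MP1104,crystal_ligand,kor,,,-6.9,-8.8,-6.5
BU27,crystal_ligand,mor,,,-5.1,-5.9,-6.6
ZINC000020559278,screened,dor,CC,-9.9,-9.9,-9.2,-7.1
ZINC000078515864,screened,dor,CC,-8.9,-8.9,-9.6,-6.7
ZINC000025329384,screened,dor,C1,-10.2,-7.7,-7.9,-7.7
ZINC000037556415,screened,dor,C1,-9.4,-7.6,-8.4,-7.6
ZINC000827360794,screened,dor,C1,-9.1,-8.2,-10.8,-8.2
ZINC000078648574,screened,dor,C1,-9.0,-6.5,-8.7,-6.5
ZINC000057999653,screened,dor,C2,-10.1,-7.7,-8.9,-7.7
ZINC000006664413,screened,dor,C2,-9.8,-5.5,-2.7,-5.5
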