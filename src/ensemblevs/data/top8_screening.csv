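compound_id,receptor_conformation,docking_score,vdw,gbele,sur,mmgbsa_total,receptor_rmsd,ligand_rmsd,gi_absorption,bbb_permeant,cyp1a2,cyp2c19,cyp2c9,cyp2d6,cyp3a4,stars,pains_alerts,brenk_alerts
DPI-287,CC,-8.6,-57.0,18.5,-51.7,-90.2,2.9,2.5,high,yes,no,no,no,yes,yes,0,0,0
ZINC000020559278,CC,-9.9,-44.7,-31.3,-40.8,-116.9,2.2,2.5,high,yes,yes,no,no,yes,yes,0,0,0
ZINC000078515864,CC,-8.9,-36.2,-25.9,-50.9,-113.1,2.6,2.7,high,yes,no,no,no,yes,no,0,0,0
ZINC000025329384,C1,-10.2,-57.2,-19.9,-57.7,-134.9,2.4,2.9,high,yes,no,no,no,yes,yes,0,0,0
ZINC000037556415,C1,-9.4,-58.5,-9.6,-43.8,-111.9,3.4,6.0,high,yes,no,yes,yes,yes,yes,0,0,0
ZINC000827360794,C1,-9.1,-43.7,-18.8,-41.6,-104.2,2.4,2.9,high,yes,no,no,no,yes,yes,0,0,0
ZINC000078648574,C1,-9.0,-50.4,-4.1,-54.1,-108.7,2.8,6.3,high,yes,no,yes,yes,yes,no,0,0,0
ZINC000057999653,C2,-10.1,-47.1,-8.6,-38.9,-94.6,2.3,2.7,high,yes,yes,yes,yes,yes,yes,0,0,0
ZINC000006664413,C2,-9.8,-46.4,-20.1,-43.4,-109.9,2.6,3.6,high,yes,yes,yes,yes,yes,yes,0,0,0
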