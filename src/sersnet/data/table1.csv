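position,assignment
494,"Ring vibration, cellulose, guanine, L-arginine"
531,"Cholesterol ester"
589,"Ascorbic acid, amide-VI"
639,"C-S stretching vibration, L-tyrosine, lactose"
725,"C-H bending vibration, adenine, coenzyme A"
812,"C-C-O stretching vibration, L-serine, glutathione"
887,"C-O-H bending vibration, glutathione, D-(+)-galactosamine"
959,"alpha-Helix, L-proline, L-valine"
1004,"C-C symmetric stretch, phenylalanine"
1073,"C-N stretching vibration, collagen"
1093,"C-N stretching vibration, D-mannos"
1135,"C-N stretching vibration, D-mannos"
1206,"Ring vibration, L-tryptophan, phenylalanine"
1330,"C-H stretching vibration, nucleic acid bases"
1443,"CH2 bending vibration, glycine, L-proline, stearic acid"
1581,"C=C bending vibration, phenylalanine, acetoacetate, riboflavin"
1654,"C=O stretching vibration, phospholipids, amide-I, alpha-Helix"
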