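order,family,species,of_pct,ra_pct,rb_pct
Cypriniformes,Xenocyprididae,Opsariichthys bidens,88.89,2.80,2.43
Cypriniformes,Xenocyprididae,Hemiculter leucisculus,100,6.01,2.63
Cypriniformes,Xenocyprididae,Culter alburnus,11.11,0.08,0.10
Cypriniformes,Xenocyprididae,Hypophthalmichthys molitrix,11.11,0.08,9.48
Cypriniformes,Gobionidae,Pseudorasbora parva,55.56,0.58,0.05
Cypriniformes,Gobionidae,Abbottina rivularis,22.22,0.16,0.02
Cypriniformes,Acheilognathidae,Rhodeus sinensis,66.67,3.21,0.27
Cypriniformes,Acheilognathidae,Rhodeus ocellatus,11.11,0.49,0.08
Cypriniformes,Cyprinidae,Spinibarbus sinensis,22.22,0.49,9.20
Cypriniformes,Cyprinidae,Onychostoma yunnanense,11.11,0.08,0.22
Cypriniformes,Cyprinidae,Onychostoma simum,22.22,0.33,0.27
Cypriniformes,Cyprinidae,Cyprinus carpio,77.78,1.07,1.09
Cypriniformes,Cyprinidae,Carassius auratus,100,22.55,14.69
Cypriniformes,Cyprinidae,Pseudogyrinocheilus prochilus,55.56,4.77,8.22
Cypriniformes,Cyprinidae,Discogobio yunnanensis,33.33,0.25,0.06
Cypriniformes,Cobitidae,Misgurnus dabryanus,11.11,0.33,0.08
Siluriformes,Siluridae,Silurus asotus,44.44,0.33,3.77
Siluriformes,Siluridae,Silurus meridionalis,11.11,0.08,0.07
Siluriformes,Bagridae,Tachysurus sinensis,33.33,1.07,0.94
Siluriformes,Bagridae,Tachysurus crassilabris,55.56,1.81,1.40
Gobiiformes,Gobiidae,Rhinogobius similis,66.67,1.15,0.03
Cichliformes,Cichlidae,Coptodon zillii,100,19.34,17.77
Centrarchiformes,Centrarchidae,Lepomis cyanellus,100,32.92,27.14
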