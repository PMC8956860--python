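taxon,group,body_shape,fixation,cycle_length,reproductive_cycles,psi_hypothesis,theta_hypothesis
Macrelmis,1,depressed,none,long,low,high,low
Phanocerus,1,depressed,none,long,low,high,low
Xenelmis,1,depressed,none,long,low,high,low
Heterelmis,2,cylindrical,none,long,low,low,low
Neoelmis,2,cylindrical,none,long,low,low,low
Ptilodactylidae,2,cylindrical,none,long,low,low,low
Dryopidae,2,cylindrical,none,long,low,low,low
Dysticidae,2,cylindrical,none,long,low,low,low
Hydrophilidae,2,cylindrical,none,long,low,low,low
Chironomidae,3,cylindrical,none,short,high,low,high
Rheotanytarsus,3,cylindrical,none,short,high,low,high
Polypedilum,3,cylindrical,none,short,high,low,high
Cryptochironomus,3,cylindrical,none,short,high,low,high
Stempellinela,3,cylindrical,none,short,high,low,high
Stenochironomus,3,cylindrical,none,short,high,low,high
Zavrelliela,3,cylindrical,none,short,high,low,high
Ceratopogonidae,4,cylindrical,none,short,moderate,low,moderate
Empididae,5,cylindrical,adhesive,short,high,moderate,high
Simuliidae,5,cylindrical,adhesive,short,high,moderate,high
Baetidae,6,cylindrical,none,moderate,moderate,low,moderate
Leptohyphidae,7,depressed,none,moderate,moderate,moderate,moderate
Leptophlebiidae,7,depressed,none,moderate,moderate,moderate,moderate
Anacroneuria,7,depressed,none,moderate,moderate,moderate,moderate
Leptohyphes,7,depressed,none,moderate,moderate,moderate,moderate
Tricorythodes,7,depressed,none,moderate,moderate,moderate,moderate
Tricorythopsis,7,depressed,none,moderate,moderate,moderate,moderate
Simothraulopsis,7,depressed,none,moderate,moderate,moderate,moderate
Gyrinidae,8,cylindrical,hooks,long,low,very high,low
Corydalus,8,cylindrical,hooks,long,low,very high,low
Protosialis,8,cylindrical,hooks,long,low,very high,low
Macronema,8,cylindrical,hooks,long,low,very high,low
Calamoceratidae,9,cylindrical,shelter,moderate,low,very high,moderate
Hydroptilidae,9,cylindrical,shelter,moderate,low,very high,moderate
Leptoceridae,9,cylindrical,shelter,moderate,low,very high,moderate
Odontoceridae,9,cylindrical,shelter,moderate,low,very high,moderate
Neotrichia,9,cylindrical,shelter,moderate,low,very high,moderate
Oecetis,9,cylindrical,shelter,moderate,low,very high,moderate
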