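isscaap_group,taxon_class,trophic_level,trophic_level_se,habitat,default_conc_wb,tonnes_per_individual,supply_group
"Tunas, bonitos, billfishes",fish,4.3,0.7,oceanic,0.38,,Pelagic Fish
"Sharks, rays, chimaeras",fish,4.1,0.5,oceanic,0.45,,Pelagic Fish
"Miscellaneous pelagic fishes",fish,3.6,0.5,coastal,0.15,,Pelagic Fish
"Herrings, sardines, anchovies",fish,2.8,0.3,coastal,0.03,,Pelagic Fish
"Cods, hakes, haddocks",fish,3.8,0.4,coastal,0.12,,Demersal Fish
"Flounders, halibuts, soles",fish,3.4,0.4,coastal,0.10,,Demersal Fish
"Miscellaneous coastal fishes",fish,3.3,0.5,coastal,0.09,,Other Marine Fish
"Shrimps, prawns",invertebrate,2.7,0.3,coastal,0.04,,Crustaceans
"Squids, cuttlefishes, octopuses",invertebrate,3.2,0.4,oceanic,0.08,,Cephalopods
"Oysters",invertebrate,2.1,0.13,coastal,0.015,,Other Molluscs
"Marine turtles",turtle,2.4,0.3,coastal,0.05,,
"Sperm-whales, pilot-whales",odontocete,4.0,0.4,oceanic,0.55,1.29,
"Blue-whales, fin-whales",mysticete,3.4,0.3,oceanic,0.05,43,
"Eared seals, hair seals, walruses",pinniped,3.9,0.4,coastal,0.25,0.231,
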