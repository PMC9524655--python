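layer,W-1,W-4,W-8,C-3,C-11,C-13,E-4,E-3,E-1
Rice's whale core distribution area,No,No,No,No,No,No,No,No,No
Rice's whale suitable habitat,No,No,No,No,No,No,No,No,No
Leatherback sea turtle high use area,No,No,No,No,No,No,No,No,No
Loggerhead sea turtle high use area,No,No,No,No,No,No,No,Yes,Yes
Loggerhead sea turtle migratory corridor,No,No,No,No,No,No,No,No,No
Hawksbill sea turtle high use area,No,No,No,No,No,No,No,No,No
Hawksbill sea turtle migratory corridor,No,No,No,No,No,No,No,No,No
Kemp's ridley sea turtle high use area,No,No,No,No,No,No,No,No,No
Green sea turtle high use area,No,No,No,No,No,No,Yes,No,No
Green sea turtle migratory corridor,No,No,No,No,No,No,No,No,No
Giant manta ray upper modeled distribution,No,No,Yes,Yes,Yes,Yes,Yes,Yes,Yes
U.S. DPS Smalltooth sawfish high use area,No,No,No,No,No,No,No,No,No
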