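statute,status,trend,population_class,score
ESA,Endangered,declining,*,0.1
ESA,Endangered,stable|unknown,small,0.1
ESA,Endangered,stable|unknown,large|unspecified,0.2
ESA,Endangered,increasing,large|unspecified,0.3
ESA,Threatened,declining|unknown,*,0.4
ESA,Threatened,stable|increasing,*,0.5
MMPA,Strategic,declining|unknown,*,0.6
MMPA,Listed,*,small,0.7
MMPA,Listed,*,large,0.8
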