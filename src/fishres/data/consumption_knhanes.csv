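species,mean_intake,extreme_intake,imputed
abalone,0.6000,13.8000,false
carp,0.4800,12.1200,false
chinese muddy loach,0.9600,43.6800,false
crucian carp,0.4800,12.1200,false
eel,1.3200,24.2400,false
far eastern catfish,0.4800,12.1200,false
flathead mullet,0.4800,12.1200,false
korean rockfish,1.2000,31.2000,false
mirror carp,0.4800,12.1200,false
olive flounder,1.3500,48.4500,false
rainbow trout,0.4800,12.1200,false
red seabream,0.4800,12.1200,false
sea bass,0.4800,12.1200,false
starry flounder,0.4800,12.1200,false
whiteleg shrimp,1.8000,50.4000,false
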