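pesticide,en15662_mean,en15662_sd,aoac_mean,aoac_sd,c18_mean,c18_sd,psa_c18_mean,psa_c18_sd
acetamiprid,87.9,4.6,77.8,6.7,75.9,0.6,75.4,1.3
azinphos-methyl,84.0,1.8,68.3,7.4,75.4,4.8,74.2,3.4
azoxystrobin,80.8,1.6,90.9,4.2,88.1,2.5,80.5,2.2
carbendazim,89.7,3.1,49.9,2.6,86.2,2.8,75.0,2.7
carbofuran,69.1,4.2,70.5,7.7,81.8,6.5,80.5,1.9
clothianidin,72.1,3.3,74.7,6.8,80.8,1.5,84.2,6.0
dichlorvos,63.5,6.4,54.4,7.0,77.2,3.0,69.7,2.0
dinotefuran,72.7,1.9,64.3,6.0,77.9,3.8,92.8,3.4
diuron,70.3,4.3,68.0,5.6,80.2,0.3,75.4,2.7
flubendiamide,89.3,4.8,55.2,1.6,80.2,2.5,73.4,4.9
hexaconazole,70.4,5.1,65.2,5.1,81.9,1.7,77.6,2.8
pyrimisulfan,86.5,4.0,77.9,4.4,83.6,4.6,265.7,26.1
terbuthylazine,76.6,3.5,57.6,3.2,81.4,4.0,76.6,1.9
thiacloprid,81.9,5.9,75.4,7.2,80.3,3.7,76.8,2.9
thiamethoxam,78.7,6.5,30.0,3.1,86.2,2.8,54.8,3.4
tricyclazole,78.4,3.2,60.8,4.7,85.4,3.7,77.5,2.4
azimsulfuron,77.6,0.3,60.8,3.1,83.3,0.5,-3.5,4.9
trifloxystrobin,74.6,4.2,59.5,1.5,82.2,1.8,80.6,1.9
difenoconazole,76.9,3.8,48.4,5.0,73.6,4.5,79.5,2.0
fenobucarb,76.5,5.9,74.6,2.8,86.4,3.1,80.7,3.4
tebufenozide,76.7,3.7,90.4,3.4,76.0,2.7,76.6,0.5
lufenuron,96.7,5.0,74.5,3.9,77.5,5.6,80.0,3.6
indoxacarb,79.4,2.8,67.8,3.6,79.1,3.3,98.4,3.2
daimuron,80.5,1.7,36.5,2.2,87.8,3.4,80.7,1.3
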