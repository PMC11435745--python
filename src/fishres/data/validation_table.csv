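pesticide,matrix,r_squared,matrix_effect,lod,loq,recovery_loq,recovery_10loq,recovery_50loq,rsd_loq,rsd_10loq,rsd_50loq
acetamiprid,eel,0.9999,16.80,0.4,5,88.8,90.1,92.7,2.2,1.4,2.8
acetamiprid,olive flounder,0.9993,-2.73,0.4,5,84.4,78.9,93.2,1.5,9.0,1.1
acetamiprid,abalone,1.0000,-5.60,0.25,3,88.9,90.1,87.9,2.8,1.1,2.9
acetamiprid,whiteleg shrimp,0.9997,-9.55,0.6,7,90.8,92.8,93.7,1.5,1.4,2.1
azinphos-methyl,eel,0.9995,24.87,0.25,3,89.7,89.8,90.7,12.1,1.9,2.5
azinphos-methyl,olive flounder,0.9990,5.85,0.25,3,84.0,86.6,93.1,6.1,3.1,4.6
azinphos-methyl,abalone,0.9989,-1.87,0.3,4,85.1,91.7,90.5,7.3,2.5,5.0
azinphos-methyl,whiteleg shrimp,0.9998,0.77,0.4,5,95.4,90.0,92.7,4.1,2.3,1.0
azoxystrobin,eel,0.9998,19.44,0.3,4,89.4,90.5,92.1,2.2,1.1,4.1
azoxystrobin,olive flounder,0.9994,-0.002,0.25,3,83.9,87.9,94.6,5.7,1.4,2.1
azoxystrobin,abalone,0.9998,-4.59,0.25,3,90.4,91.4,91.4,7.1,3.3,2.9
azoxystrobin,whiteleg shrimp,0.9995,-5.99,0.3,4,85.8,93.8,94.0,5.7,1.5,3.3
carbendazim,eel,0.9995,15.06,0.3,4,86.7,85.8,88.6,4.5,3.4,4.9
carbendazim,olive flounder,0.9989,-8.80,0.6,7,80.2,79.0,87.7,4.1,3.5,2.1
carbendazim,abalone,0.9999,-11.90,0.4,5,86.7,88.3,85.7,3.9,1.9,4.7
carbendazim,whiteleg shrimp,0.9992,-15.11,0.25,3,87.6,91.0,89.1,8.4,3.3,5.2
carbofuran,eel,0.9996,24.36,0.25,3,91.8,88.8,92.7,4.7,1.2,3.8
carbofuran,olive flounder,0.9994,0.83,0.25,3,87.2,87.9,93.7,4.2,1.4,1.4
carbofuran,abalone,0.9998,-0.31,0.3,4,93.4,89.5,88.4,5.0,0.7,2.9
carbofuran,whiteleg shrimp,0.9995,-4.04,0.4,5,90.0,92.3,94.1,5.2,2.1,2.2
clothianidin,eel,0.9994,23.75,0.25,3,95.4,91.0,93.9,5.1,4.2,4.0
clothianidin,olive flounder,0.9992,-2.45,0.3,4,75.2,83.4,91.0,11.2,1.9,2.9
clothianidin,abalone,0.9997,-6.90,0.3,4,85.8,88.6,85.9,10.5,3.7,2.4
clothianidin,whiteleg shrimp,0.9983,-6.53,0.4,5,84.2,92.5,91.5,2.8,2.7,2.0
dichlorvos,eel,0.9996,15.87,0.4,5,84.0,88.1,92.7,7.1,2.1,1.7
dichlorvos,olive flounder,0.9988,-4.16,0.4,5,82.7,85.1,93.7,8.5,1.5,3.2
dichlorvos,abalone,0.9999,-6.48,0.8,10,88.9,90.8,91.4,5.6,2.4,2.7
dichlorvos,whiteleg shrimp,0.9993,-9.03,0.8,10,71.7,89.7,92.6,9.9,1.6,2.3
dinotefuran,eel,0.9998,5.45,0.3,4,87.1,88.9,91.4,5.3,1.6,1.6
dinotefuran,olive flounder,0.9990,-1.80,0.3,4,82.1,84.8,90.2,3.9,2.5,1.6
dinotefuran,abalone,0.9999,-9.93,0.4,5,89.2,88.7,87.1,6.5,1.3,3.0
dinotefuran,whiteleg shrimp,0.9996,25.45,0.4,5,88.1,89.5,91.9,1.6,2.7,2.0
diuron,eel,0.9996,27.79,0.4,5,91.5,89.0,92.0,4.3,1.6,1.6
diuron,olive flounder,0.9991,-1.96,0.25,3,84.8,83.5,92.0,5.7,1.8,0.5
diuron,abalone,0.9999,-3.49,0.3,4,93.2,89.3,89.6,3.6,1.9,2.1
diuron,whiteleg shrimp,0.9991,-3.49,0.3,4,93.2,89.3,89.6,3.6,1.9,2.1
flubendiamide,eel,0.9991,21.29,0.25,3,88.3,87.3,88.5,6.2,2.7,5.9
flubendiamide,olive flounder,0.9976,7.12,0.4,4,92.8,88.8,95.1,5.6,3.1,3.8
flubendiamide,abalone,0.9995,2.04,0.4,4,86.2,93.4,90.7,8.1,1.5,4.3
flubendiamide,whiteleg shrimp,0.9965,0.89,0.25,3,95.3,92.8,93.7,10.7,4.1,4.9
hexaconazole,eel,0.9921,-1.77,0.25,3,88.3,93.9,97.1,4.9,1.2,3.8
hexaconazole,olive flounder,0.9988,-2.58,0.25,3,83.7,84.9,89.3,5.8,3.2,2.9
hexaconazole,abalone,0.9996,-8.25,0.25,3,77.6,90.5,87.9,13.2,2.3,3.1
hexaconazole,whiteleg shrimp,0.9990,-7.47,0.25,3,82.9,91.4,92.9,5.8,2.9,5.2
pyrimisulfan,eel,0.9998,13.62,0.4,5,90.3,89.0,92.2,1.9,1.2,3.8
pyrimisulfan,olive flounder,0.9990,6.35,0.3,4,87.6,86.6,93.4,2.0,1.2,1.1
pyrimisulfan,abalone,0.9996,1.08,0.25,3,90.2,90.2,89.2,2.7,1.1,2.5
pyrimisulfan,whiteleg shrimp,0.9997,3.16,0.3,4,88.6,90.9,92.8,1.2,1.8,2.1
terbuthylazine,eel,0.9995,28.46,0.4,5,88.8,86.7,90.1,2.6,0.6,3.7
terbuthylazine,olive flounder,0.9994,-1.35,0.25,3,87.0,85.7,90.9,5.1,1.8,1.5
terbuthylazine,abalone,0.9999,-5.93,0.3,4,90.1,91.6,89.7,4.4,1.3,2.9
terbuthylazine,whiteleg shrimp,0.9994,-4.81,0.3,4,82.4,92.1,91.5,6.2,3.5,3.8
thiacloprid,eel,0.9999,20.48,0.4,5,84.8,90.3,91.9,2.8,1.2,4.2
thiacloprid,olive flounder,0.9995,0.82,0.4,5,85.0,86.0,92.5,2.3,1.9,1.1
thiacloprid,abalone,0.9939,-2.12,0.3,4,88.4,89.9,86.7,2.8,1.7,0.4
thiacloprid,whiteleg shrimp,0.9994,-6.37,0.6,7,86.1,93.0,93.0,2.4,1.3,1.4
thiamethoxam,eel,0.9997,16.73,0.25,3,93.4,90.2,93.9,7.7,1.1,2.7
thiamethoxam,olive flounder,0.9995,-11.66,0.6,7,81.2,82.5,91.9,2.8,2.6,1.8
thiamethoxam,abalone,1.0000,-14.10,0.3,4,90.6,89.0,87.5,5.1,1.1,2.3
thiamethoxam,whiteleg shrimp,0.9991,-6.82,0.4,5,85.0,92.1,94.2,4.5,2.3,2.4
tricyclazole,eel,0.9997,-0.08,0.25,3,90.1,90.7,101.3,3.3,0.8,2.4
tricyclazole,olive flounder,0.9993,-20.33,0.4,5,86.3,87.3,106.3,1.0,2.0,1.9
tricyclazole,abalone,0.9998,-19.23,0.4,5,85.6,88.9,93.9,5.1,0.8,2.2
tricyclazole,whiteleg shrimp,0.9979,-26.81,0.3,4,90.6,95.4,101.0,3.6,1.1,1.7
azimsulfuron,eel,0.9998,15.92,0.3,4,87.5,88.2,91.1,3.1,1.5,2.2
azimsulfuron,olive flounder,0.9993,6.15,0.3,4,83.0,83.4,90.5,3.6,1.7,1.9
azimsulfuron,abalone,0.9997,1.80,0.3,4,85.8,90.0,89.2,3.7,2.1,2.1
azimsulfuron,whiteleg shrimp,0.9997,4.49,0.25,3,85.1,88.2,90.9,3.8,1.7,2.8
trifloxystrobin,eel,0.9990,27.81,0.4,5,96.8,90.9,92.7,4.5,3.0,3.8
trifloxystrobin,olive flounder,0.9984,-3.56,0.25,3,90.4,90.5,95.8,2.7,2.3,1.8
trifloxystrobin,abalone,0.9998,-3.16,0.25,3,87.8,90.5,88.7,4.3,2.1,2.1
trifloxystrobin,whiteleg shrimp,0.9986,-10.76,0.25,3,87.1,94.6,100.5,7.8,2.1,1.5
difenoconazole,eel,0.9993,16.22,0.3,4,86.3,88.7,92.5,1.8,1.4,2.2
difenoconazole,olive flounder,0.9990,1.25,0.3,4,83.0,86.1,91.9,3.4,0.7,1.0
difenoconazole,abalone,1.0000,-5.08,0.25,3,87.6,91.8,90.5,5.8,0.8,2.5
difenoconazole,whiteleg shrimp,0.9996,-4.78,0.25,3,86.3,92.3,91.7,4.8,1.5,2.4
fenobucarb,eel,0.9997,18.71,0.3,4,87.6,88.9,92.2,3.9,1.8,2.2
fenobucarb,olive flounder,0.9990,-0.45,0.3,4,81.7,86.0,91.7,7.4,1.2,2.3
fenobucarb,abalone,0.9997,-4.37,0.3,4,88.7,92.2,89.1,5.3,1.8,2.9
fenobucarb,whiteleg shrimp,0.9994,-2.13,0.25,3,90.1,93.7,93.1,3.1,1.7,2.0
tebufenozide,eel,0.9998,22.51,0.25,3,92.1,90.6,93.9,2.8,1.8,3.9
tebufenozide,olive flounder,0.9993,0.71,0.4,5,83.1,86.8,94.4,3.6,1.7,1.6
tebufenozide,abalone,0.9998,-3.82,0.3,4,84.2,91.5,89.0,4.6,1.7,1.9
tebufenozide,whiteleg shrimp,0.9989,-3.61,0.4,5,90.5,91.6,93.8,3.7,2.1,4.3
lufenuron,eel,0.9993,20.25,0.4,5,87.6,86.6,87.2,5.3,2.4,6.7
lufenuron,olive flounder,0.9997,-10.19,0.4,5,78.8,91.9,91.6,12.0,7.0,3.1
lufenuron,abalone,0.9997,-17.85,0.3,4,80.4,91.9,84.1,14.2,2.2,6.9
lufenuron,whiteleg shrimp,0.9992,-3.16,0.25,3,93.7,94.0,95.0,12.9,2.5,4.9
indoxacarb,eel,0.9997,15.40,0.4,5,90.8,89.2,92.6,2.2,2.4,5.1
indoxacarb,olive flounder,0.9976,5.46,0.3,4,81.6,88.7,93.7,12.5,2.6,2.7
indoxacarb,abalone,0.9997,-1.23,0.4,5,94.1,90.9,90.5,7.7,2.0,1.2
indoxacarb,whiteleg shrimp,0.9988,-2.55,0.3,4,89.2,90.8,92.8,7.2,2.3,6.6
daimuron,eel,0.9998,16.93,0.3,4,87.2,88.9,91.4,1.3,1.5,3.6
daimuron,olive flounder,0.9993,1.61,0.3,4,87.2,86.7,93.1,1.7,0.8,0.9
daimuron,abalone,0.9999,-2.36,0.25,3,88.7,91.4,90.4,1.6,0.9,2.3
daimuron,whiteleg shrimp,0.9997,-3.47,0.25,3,89.1,91.6,93.3,3.0,1.6,2.7
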