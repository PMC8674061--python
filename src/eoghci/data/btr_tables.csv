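architecture,subject,max_accuracy,min_accuracy,mean_accuracy,btr
ernn,S1,93.64,83.64,90.73,81.17
ernn,S2,93.64,87.27,90.86,81.43
ernn,S3,94.55,85.45,90.94,81.59
ernn,S4,93.64,86.36,90.90,81.51
ernn,S5,93.78,85.45,90.58,80.87
ernn,S6,93.64,86.36,90.59,80.89
ernn,S7,93.64,85.56,90.77,81.25
ernn,S8,93.64,86.36,90.90,81.51
ernn,S9,94.55,85.45,90.91,81.53
ernn,S10,93.64,84.55,90.31,80.34
ernn,S11,93.64,86.36,90.58,80.87
ernn,S12,95.55,88.18,91.91,83.55
ernn,S13,93.64,86.36,90.90,81.51
ernn,S14,93.64,86.36,91.12,81.95
ernn,S15,94.55,87.09,90.71,81.13
ernn,S16,94.55,85.56,90.77,81.25
ernn,S17,93.64,86.36,90.68,81.07
ernn,S18,93.64,85.56,90.77,81.25
ernn,S19,93.64,87.27,90.82,81.35
ernn,S20,94.55,86.36,90.64,80.99
dtdnn,S1,93.64,86.36,90.41,80.53
dtdnn,S2,93.72,85.56,90.49,80.69
dtdnn,S3,93.74,86.36,90.40,80.51
dtdnn,S4,92.74,86.36,90.58,80.87
dtdnn,S5,93.64,85.45,90.32,80.36
dtdnn,S6,93.64,85.56,90.13,79.98
dtdnn,S7,93.64,85.45,90.59,80.89
dtdnn,S8,93.64,86.36,90.49,80.69
dtdnn,S9,93.64,85.45,90.34,80.39
dtdnn,S10,93.64,86.36,90.23,80.18
dtdnn,S11,94.55,85.56,90.47,80.65
dtdnn,S12,94.55,88.18,91.76,83.24
dtdnn,S13,94.55,86.36,90.63,80.97
dtdnn,S14,94.55,85.45,90.86,81.42
dtdnn,S15,93.64,86.36,90.50,80.71
dtdnn,S16,94.55,85.55,90.59,80.89
dtdnn,S17,93.64,86.36,90.54,80.79
dtdnn,S18,93.64,86.36,90.59,80.89
dtdnn,S19,93.64,85.45,90.58,80.87
dtdnn,S20,94.55,86.36,90.73,81.16
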