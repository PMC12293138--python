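subject,n_channels,kernel,Acc,Sen,Spec,Pre,F1
aa,19,linear,66.96,81.67,50.00,65.33,72.59
al,19,linear,100.00,100.00,100.00,100.00,100.00
av,19,linear,74.49,78.57,70.41,72.64,75.49
aw,19,linear,83.04,83.64,82.46,82.14,82.88
ay,19,linear,93.65,97.54,90.00,90.15,93.70
aa,19,rbf,66.96,75.00,57.69,67.16,70.87
al,19,rbf,100.00,100.00,100.00,100.00,100.00
av,19,rbf,72.45,80.61,64.29,69.30,74.53
aw,19,rbf,82.59,80.91,84.21,83.18,82.03
ay,19,rbf,88.89,97.54,80.77,82.64,89.47
aa,30,linear,72.32,81.67,61.54,71.01,75.97
al,30,linear,100.00,100.00,100.00,100.00,100.00
av,30,linear,74.49,83.67,65.31,70.69,76.64
aw,30,linear,83.04,83.64,82.46,82.14,82.88
ay,30,linear,93.65,93.44,93.85,93.44,93.44
aa,30,rbf,68.75,70.00,67.31,71.19,70.59
al,30,rbf,100.00,100.00,100.00,100.00,100.00
av,30,rbf,72.45,82.65,62.24,68.64,75.00
aw,30,rbf,83.48,83.64,83.33,82.88,83.26
ay,30,rbf,87.30,95.90,79.23,81.25,87.97
aa,61,linear,72.32,70.00,75.00,76.36,74.04
al,61,linear,100.00,100.00,100.00,100.00,100.00
av,61,linear,71.43,84.69,58.16,66.94,74.77
aw,61,linear,87.05,86.36,87.72,87.16,86.76
ay,61,linear,92.86,96.72,89.23,89.39,92.91
aa,61,rbf,71.43,68.33,75.00,75.93,71.93
al,61,rbf,100.00,100.00,100.00,100.00,100.00
av,61,rbf,70.92,73.47,68.37,69.90,71.64
aw,61,rbf,87.50,85.45,89.47,88.68,87.04
ay,61,rbf,85.71,99.18,73.08,77.56,87.05
aa,118,linear,69.64,65.00,75.00,75.00,69.64
al,118,linear,100.00,100.00,100.00,100.00,100.00
av,118,linear,68.37,80.61,56.12,64.75,71.82
aw,118,linear,89.29,86.36,92.11,91.35,88.79
ay,118,linear,92.46,93.44,91.54,91.20,92.31
aa,118,rbf,66.07,48.33,86.54,80.56,60.42
al,118,rbf,100.00,100.00,100.00,100.00,100.00
av,118,rbf,66.84,70.41,63.27,65.71,67.98
aw,118,rbf,90.18,89.09,91.23,90.74,89.91
ay,118,rbf,82.54,95.90,70.00,75.00,84.17
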