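# idealized 10-05 electrode positions projected to the unit sphere
# columns: name x y z  (x right, y anterior, z superior)
Fpz -0.008303709 0.999675597 -0.024077991
Fp2 0.272615928 0.959233125 -0.074514211
Fp1 -0.288482774 0.954619416 -0.074023376
AFz -0.007278176 0.942411980 0.334375071
AF2 0.181294555 0.934118031 0.307499250
AF1 -0.187735598 0.932627959 0.308156512
AF3 -0.340473746 0.918659044 0.200357653
AF4 0.337648544 0.918557210 0.205538591
AF6 0.449151299 0.891976144 0.051397175
AF5 -0.459324252 0.886798551 0.051083862
AFF1h -0.122588150 0.863690806 0.488886835
AFF2h 0.122360652 0.861290092 0.493160470
AF8 0.531902953 0.839313205 -0.112394804
AF7 -0.544108324 0.831617102 -0.111171617
AFF6h 0.518715603 0.825505823 0.222428099
AFF5h -0.525657819 0.820101316 0.226092213
Fz -0.006731142 0.753590092 0.657310174
F2 0.288332187 0.751423775 0.593487034
F1 -0.287938967 0.744921657 0.601816315
F4 0.529175569 0.739409354 0.416229532
F3 -0.533603034 0.727683462 0.430980952
F6 0.699533043 0.695870390 0.162535909
F5 -0.700084947 0.692968355 0.172267018
F8 0.755436894 0.641298016 -0.134357557
F7 -0.762390771 0.633732687 -0.130932019
FFC4h 0.472950278 0.615289024 0.630664294
FFC2h 0.166934479 0.611173542 0.773692304
FFC1h -0.165520898 0.609392117 0.775399304
FFC3h -0.476544877 0.603754159 0.639050777
FFC6h 0.715767584 0.590301625 0.373122978
FFC5h -0.719920705 0.578110228 0.384060859
F10 0.673702321 0.557076957 -0.485582586
F9 -0.676508746 0.555794659 -0.483144093
FFT8h 0.839578182 0.541768011 0.039948713
FFT7h -0.842734133 0.536446452 0.044993160
FC2 0.354504836 0.452968672 0.818013266
FCz -0.006187443 0.448942083 0.893539435
FC1 -0.362930385 0.442818369 0.819874032
FC4 0.668878503 0.441554822 0.598022481
FC3 -0.671629254 0.433349424 0.600934624
FC6 0.874185472 0.408273908 0.262891949
FC5 -0.878320679 0.397526793 0.265565875
FT8 0.920207742 0.366193959 -0.138273987
FT7 -0.926909707 0.349973387 -0.135488094
FT10 0.810646771 0.303417923 -0.500788755
FT9 -0.816904608 0.300762211 -0.492147289
FCC2h 0.185326172 0.270636486 0.944674601
FCC4h 0.552829102 0.266608134 0.789493563
FCC1h -0.197565069 0.265880249 0.943544242
FCC3h -0.558153350 0.256649314 0.789047507
FCC6h 0.836940263 0.243155603 0.490312501
FCC5h -0.838286425 0.233208342 0.492838451
FTT8h 0.971539577 0.219088848 0.090060691
FTT7h -0.974437714 0.205504616 0.090768904
Cz -0.005851917 0.076040270 0.997087575
C2 0.385229383 0.074819925 0.919782747
C1 -0.384427304 0.070025762 0.920495541
C4 0.723854700 0.064022946 0.686975571
C3 -0.721066855 0.055625894 0.690628953
C6 0.944557113 0.045507004 0.325178370
C5 -0.943645470 0.034719024 0.329131914
T8 0.992367550 0.020406837 -0.121614997
T7 -0.992917180 0.008523573 -0.118502419
CCP2h 0.192565215 -0.114109619 0.974626920
CCP1h -0.193429452 -0.115749123 0.974262381
CCP4h 0.557981770 -0.119953152 0.821137982
CCP3h -0.556875014 -0.125563954 0.821050493
CCP6h 0.840364925 -0.131800612 0.525752215
CCP5h -0.839398381 -0.140794406 0.524964087
TTP8h 0.981196625 -0.150853816 0.120400622
TTP7h -0.980590057 -0.157247352 0.117117080
TP9 -0.843138552 -0.289780940 -0.452928679
CPz -0.005798185 -0.296070788 0.955148402
CP2 0.366793060 -0.297396610 0.881486306
TP10 0.837171426 -0.297664851 -0.458845987
CP1 -0.356945547 -0.298703121 0.885079840
CP4 0.677088922 -0.308355384 0.668182272
CP3 -0.669932825 -0.314090715 0.672708728
CP6 0.889703831 -0.317162251 0.328382703
TP8 0.942900605 -0.321074556 -0.088597854
TP7 -0.942905634 -0.321632843 -0.086494390
CP5 -0.885046147 -0.327332196 0.330978777
CPP2h 0.174868116 -0.463321646 0.868765903
CPP4h 0.486784786 -0.467615102 0.737818872
CPP1h -0.161467315 -0.469377584 0.868108858
CPP3h -0.475670265 -0.476092664 0.739644222
CPP6h 0.731619323 -0.478707067 0.485358331
CPP5h -0.725644965 -0.485429354 0.487645083
TPP8h 0.863318779 -0.486385554 0.134572580
TPP7h -0.861846935 -0.489180177 0.133875375
P9 -0.722989935 -0.557101839 -0.408562229
P10 0.714759285 -0.565067424 -0.412089762
P7 -0.790938110 -0.610860706 -0.035582353
P2 0.297946814 -0.613874957 0.731016575
P8 0.787425530 -0.615318341 -0.036665706
Pz -0.006338299 -0.618371389 0.785860453
P4 0.549072605 -0.620649151 0.559744500
P1 -0.288749388 -0.622031134 0.727805646
P3 -0.545329221 -0.626600087 0.556765994
P5 -0.720932106 -0.628876688 0.291154617
P6 0.716485915 -0.633504211 0.292096471
PPO5h -0.558138287 -0.742386528 0.370599374
PPO6h 0.550161138 -0.747825090 0.371591654
PPO2h 0.127423337 -0.747949431 0.651409964
PPO1h -0.129612552 -0.754463854 0.643416567
PO9 -0.531742667 -0.773382871 -0.345150214
PO10 0.518336942 -0.780737586 -0.348963661
PO7 -0.568416020 -0.822495221 0.020120628
PO8 0.560006884 -0.828256024 0.019602253
PO3 -0.378751694 -0.849541059 0.367188159
PO4 0.364969957 -0.857436368 0.362766875
POz -0.007775293 -0.863933852 0.503545275
POO1 -0.147972388 -0.934535804 0.323646416
POO2 0.129291250 -0.942738424 0.307454120
O1 -0.301771961 -0.950047275 0.079648350
O2 0.288597204 -0.954115518 0.079845048
Iz -0.009369738 -0.973507787 -0.228461804
Oz -0.008846518 -0.990162379 0.139643127
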