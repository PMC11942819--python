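execution,V01,V02,V03,V04,V05,V06,V07,V08,V09,V10
Ex1_25,4.20,10.41,0.88,4.56,3.90,6.71,9.23,4.33,0.55,4.44
Ex2_25,4.07,4.69,5.03,3.82,0.97,2.48,2.62,0.13,4.27,3.78
Ex3_25,5.25,0.98,4.10,5.32,1.35,1.82,0.5,2.73,7.79,4.18
Ex1_50,6.12,4.58,2.47,4.57,5.61,0.15,4.38,1.24,1.45,2.99
Ex2_50,5.42,3.58,0.89,4.98,4.03,10.15,1.39,3.03,0.44,5.63
Ex3_50,7.55,2.30,0.69,7.63,6.86,4.35,3.63,0.93,1.94,4.05
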