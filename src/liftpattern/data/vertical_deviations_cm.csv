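execution,V01,V02,V03,V04,V05,V06,V07,V08,V09,V10
Ex1_25,1.29,5.61,2.11,0.87,4.25,10.88,18.32,6.03,5.31,10.00
Ex2_25,0.64,5.02,6.27,4.03,3.11,4.43,7.59,1.49,12.01,7.63
Ex3_25,0.68,9.27,5.82,6.31,2.58,3.95,3.01,3.21,9.44,5.03
Ex1_50,7.14,2.82,6.53,15.45,6.51,24.43,15.19,7.94,17.35,15.23
Ex2_50,5.62,6.36,1.48,16.03,4.60,13.69,12.27,3.92,11.87,18.06
Ex3_50,11.8,9.08,0.53,13.78,14.48,18.63,13.82,3.80,11.23,18.54
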