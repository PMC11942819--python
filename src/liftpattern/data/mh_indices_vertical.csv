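execution,V01,V02,V03,V04,V05,V06,V07,V08,V09,V10
Ex1_50,0.99807,0.99948,0.99709,0.98621,0.99712,0.97582,0.98924,0.99626,0.98587,0.98458
Ex2_50,0.99877,0.99744,0.99983,0.98526,0.99853,0.99155,0.99277,0.99904,0.99299,0.97906
Ex3_50,0.99507,0.99495,0.99998,0.98882,0.98705,0.98510,0.99097,0.99910,0.99369,0.97806
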