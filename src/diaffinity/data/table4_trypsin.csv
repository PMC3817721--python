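complex_id,dg_exptl,DIAV_L,DIAV_LW,DIAV_LC
1tng,-4.00,-5.45,-5.36,-2.69
1tnh,-4.59,-5.29,-5.20,-5.50
3ptb,-6.46,-4.92,-4.83,-5.15
1pph,-8.48,-8.32,-8.30,-8.51
1ppc,-8.80,-9.32,-9.31,-9.53
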