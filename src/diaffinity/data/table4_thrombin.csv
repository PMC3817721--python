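complex_id,dg_exptl,DIAV_L,DIAV_LW,DIAV_LC
1dwb,-3.98,-5.15,-5.02,-5.57
1ett,-8.44,-9.9,-9.74,-9.81
1etr,-10.09,-9.9,-9.89,-10.22
1ets,-11.62,-10.9,-10.76,-10.46
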