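complex_id,dg_exptl,dg_original,alprenolol,alprenolol_diff,fenoterol,fenoterol_diff,cetirizine,cetirizine_diff
1abe2,-9.57,-8.06,-6.85,-1.22,-8.21,0.14,-9.28,1.22
1abf1,-7.39,-8.40,-6.13,-2.27,-6.72,-1.68,-7.93,-0.47
1apu,-10.50,-11.63,-2.77,-8.86,-4.50,-7.12,-5.69,-5.93
1cbx,-8.65,-8.89,-5.84,-3.04,-7.51,-1.38,-8.30,-0.58
1dog,-5.48,-9.05,-5.18,-3.87,-7.75,-1.30,-5.08,-3.97
1dwb,-3.98,-5.45,-5.44,-0.01,-6.56,1.11,-8.24,2.80
1ebg,-14.76,-6.74,0.00,-6.74,0.00,-6.74,0.00,-6.74
1epo,-10.85,-14.42,-5.64,-8.78,-7.30,-7.12,-8.49,-5.93
1rbp,-9.17,-8.76,,,,,-8.69,-0.08
1stp,-18.27,-6.59,,,,,-5.96,-0.63
1tnh,-4.59,-5.59,-4.39,-1.20,-5.62,0.03,-6.13,0.54
1ulb,-7.23,-6.19,-5.45,-0.74,-6.23,0.04,-8.98,2.79
2gbp,-10.36,-10.14,-7.16,-2.98,-8.74,-1.40,-10.24,0.11
2ifb,-7.41,-8.60,-5.81,-2.79,-7.09,-1.51,-9.01,0.41
2tsc,-11.62,-8.23,-5.68,-2.55,-6.48,-1.75,-8.69,0.47
2ypi,-6.58,-6.92,-4.68,-2.24,,,,
3ptb,-6.46,-4.96,-4.49,-0.48,-5.89,0.93,-5.64,0.68
4dfr,-13.22,-8.42,-5.16,-3.26,-5.64,-2.79,-6.66,-1.76
6cpa,-15.71,-11.68,-6.82,-4.86,-7.77,-3.91,-9.75,-1.93
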