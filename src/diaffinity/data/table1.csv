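complex_id,dg_exptl,DIAV,DIAS,DIAV_L,DIAV_W,DIAV_LW,DIAV_LC
1abf,-7.39,-6.44,-7.46,-7.33,-6.35,-7.16,-7.68
1apu,-10.50,-9.70,-10.70,-9.00,-9.70,-9.30,-10.45
1dbb,-12.27,-11.89,-11.25,-12.08,-11.67,-13.09,-12.80
1dbj,-10.47,-11.28,-10.39,-11.35,-11.07,-9.24,-9.19
1dog,-5.48,-6.45,-8.58,-8.00,-6.38,-8.28,-8.64
1dwb,-3.98,-5.04,-5.16,-5.24,-4.92,-5.57,-5.65
1epo,-10.85,-12.49,-12.35,-13.13,-12.53,-10.79,-10.85
1etr,-10.09,-10.95,-9.86,-9.90,-10.87,-10.38,-10.23
1ets,-11.62,-10.75,-10.21,-10.48,-10.62,-10.43,-9.51
1ett,-8.44,-12.04,-10.87,-10.42,-11.76,-8.44,-10.53
1hpv,-12.57,-13.29,-13.32,-12.78,-13.33,-12.22,-13.15
1hsl,-9.96,-6.79,-7.86,-7.26,-6.74,-5.43,-7.74
1htf,-11.04,-12.10,-10.45,-11.48,-12.13,-11.19,-11.97
1hvr,-12.97,-15.58,-14.97,-15.33,-15.63,-14.42,-15.18
1nsd,-7.23,-8.76,-9.21,-9.19,-8.65,-10.07,-9.92
1pgp,-7.77,-9.81,-9.10,-8.99,-9.56,-6.98,-8.00
1phg,-11.81,-9.63,-9.57,-10.59,-9.53,-9.58,-11.04
1ppc,-8.80,-9.09,-8.55,-9.44,-9.10,-8.40,-9.56
1pph,-8.49,-7.83,-7.46,-8.13,-7.81,-7.63,-8.51
1rbp,-9.17,-9.10,-9.62,-9.74,-9.11,-9.04,-9.76
1tng,-4.00,-5.03,-5.39,-5.48,-4.98,-4.82,-2.64
1tnh,-4.59,-4.89,-5.53,-5.26,-4.83,-4.78,-5.52
1ulb,-7.23,-6.18,-5.90,-6.06,-5.99,-6.10,-6.25
2cgr,-9.92,-12.21,-11.20,-11.16,-11.99,-11.19,-8.41
2gbp,-10.36,-7.55,-9.23,-8.63,-7.45,-10.09,-9.37
2ifb,-7.41,-8.13,-7.89,-7.08,-8.15,-8.63,-7.48
2phh,-6.38,-7.04,-7.57,-7.31,-6.83,-8.47,-7.95
2r04,-8.48,-10.72,-10.58,-10.29,-10.71,-12.11,-10.48
2tsc,-11.62,-8.63,-9.97,-8.90,-8.75,-9.76,-8.09
2ypi,-6.58,-5.87,-6.53,-6.20,-5.76,-7.16,-6.64
3ptb,-6.46,-4.17,-4.75,-4.75,-4.12,-5.59,-5.11
4dfr,-13.23,-8.35,-7.96,-8.16,-8.36,-9.25,-8.14
5abp,-9.05,-6.86,-8.12,-7.46,-6.77,-8.87,-8.21
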