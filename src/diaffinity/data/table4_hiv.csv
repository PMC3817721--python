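complex_id,dg_exptl,DIAV_L,DIAV_LW,DIAV_LC
1k6p,-8.84,-11.71,-11.74,-11.78
1ajv,-10.59,-10.36,-10.39,-10.13
1ajx,-10.86,-9.89,-9.91,-9.68
1hih,-10.97,-11.67,-11.67,-11.73
1htf,-11.04,-11.57,-11.59,-11.86
1aaq,-11.45,-13.15,-13.13,-12.96
1hpv,-12.57,-12.79,-12.87,-13.06
1hvr,-12.97,-14.79,-14.93,-14.65
1hvk,-13.79,-13.63,-13.65,-13.70
1vj,-14.62,-12.82,-12.85,-12.89
1dif,-14.63,-13.76,-13.77,-13.82
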