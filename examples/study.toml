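# Phantom-study configuration: front snapshot at t* = 60 time units,
# about 1.5x the phantom organ's minor semi-axis.
[fm]
t_star = 60.0
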