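# Reported SIM coniine marks for 17 Sarracenia accessions (lid / pitcher).
# x = present, x* = trace (close to the 1 ug/ml limit of detection),
# - = not detected, na = tissue not analysed.
species	sample	lid	pitcher
Sarracenia alata 'Black Tube'		x	x*
Sarracenia alata		x	x
Sarracenia flava	20	x*	-
Sarracenia flava var. atropurpurea		x*	x*
Sarracenia flava var. maxima	44	x*	x*
Sarracenia flava var. ornata		x	x*
Sarracenia leucophylla		x	na
Sarracenia minor var. okefenokeensis	5	x	-
Sarracenia oreophila		-	x
Sarracenia psittacina	13	na	x
Sarracenia psittacina	43	x	x
Sarracenia purpurea subsp. burkii		x	x
Sarracenia purpurea subsp. venosa	36	x	x
Sarracenia purpurea subsp. venosa var. burkii f. luteola	48	x	x
Sarracenia purpurea subsp. venosa var. montana	41	x	x
Sarracenia rubra subsp. alabamensis		x	x
Sarracenia rubra subsp. gulfensis		x	x
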