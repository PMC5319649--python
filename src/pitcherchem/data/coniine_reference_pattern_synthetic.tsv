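# Stand-in (synthetic) relative ion intensities for a pure coniine
# standard, normalised to the base peak m/z 84 = 1.0.  m/z 126 is the
# molecular ion.  The real standard's spectrum is instrument-specific;
# override with your own pattern for real data.
mz	ratio
56	0.35
70	0.18
80	0.14
84	1.00
126	0.10
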