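bath_thickness_mm,g_total_ms_10khz,g_total_ms_20khz,g_total_ms_40khz
0.000,4.6579,4.6579,4.7826
2.118,6.4886,6.6399,6.6144
4.868,8.3578,8.6467,7.9449
11.668,11.3277,11.9102,11.6696
20.868,12.8155,13.4538,12.4735
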