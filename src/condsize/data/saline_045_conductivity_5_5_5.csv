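frequency_hz,1.75,3,4,6,8
10000,1.7000,1.6000,0.9500,0.8800,0.8000
20000,2.2000,1.6000,1.0000,0.9000,0.8100
40000,2.4000,1.6000,1.0300,0.9200,0.8200
60000,2.6000,1.7000,1.0400,0.9500,0.8300
80000,2.8000,1.8000,1.0600,0.9500,0.8300
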