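lat,lon,fallout_bq_m2_yr
48.5,-123.3,162
45.5,-122.6,178
40.8,-124.1,151
37.8,-122.4,143
34.0,-118.4,112
32.7,-117.2,101
41.5,-112.0,128
47.6,-117.4,171
44.0,-116.9,139
36.1,-115.1,92
40.0,-105.3,131
29.8,-95.4,118
41.9,-87.6,168
40.7,-74.0,182
25.8,-80.2,108
38.9,-77.0,158
30.0,-90.1,137
35.2,-80.8,149
43.6,-79.4,166
21.3,-157.9,78
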