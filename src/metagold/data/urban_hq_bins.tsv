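bin_id	completeness	contamination
Grip5941_1	100	0.11
Grip6354_1	100	0.55
Grip6358_1	98.9	1.23
Grip6361_3	98.93	2.34
Pole5898_1	99.34	0.55
Pole6380_1	99.12	4.23
Sb5919_4	99.01	0.66
Sb5948_2	100	0.13
Ts5934_1	99.78	1.75
Ts5963_1	99.56	0
Ts6363_1	100	0.11
Ts6367_1	100	0
Ts6375_2	99.34	1.86
Ts5059_2	100	0
Metal8994_2	99.36	0.14
Metal8994_5	99.07	0.63
Metal9078_4	98.77	2.9
Metal9087_2	100	0.65
Metal9150_4	99.3	1.4
Metal9150_5	99.57	0.42
Metal9150_7	100	0.26
Metal9957_3	94.52	0.27
Metal0032_2	99.83	0.16
MePl9373_2	99.59	0.2
MePl9832_7	98.59	3.76
Wood9044_4	99.47	0.33
Wood9200_3	100	0
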