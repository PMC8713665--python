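# Longitudinal serosal SO2 profiles (%) of seven resected colon segments,
# proximal (1 cm) to distal (10 cm), 1 cm divisions.
position_cm	P1	P2	P3	P4	P5	P6	P7
1	82.14	81.91	78.37	76.50	78.11	77.33	76.21
2	81.54	79.56	77.06	77.41	80.05	79.08	77.52
3	79.38	77.45	75.45	76.37	80.65	79.02	77.89
4	79.82	78.92	75.01	78.25	81.38	79.57	78.64
5	80.30	79.33	75.33	75.47	77.95	75.12	74.27
6	77.64	75.76	74.37	73.10	78.38	75.43	73.93
7	70.20	70.18	72.49	72.08	77.80	75.08	73.42
8	70.72	70.80	74.52	74.41	79.81	77.56	75.83
9	72.84	70.61	73.63	72.69	79.39	76.58	74.76
10	71.14	69.50	73.61	71.39	75.45	70.61	71.04
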