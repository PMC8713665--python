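# Surgeon-chosen transection point (cm from proximal end) per segment.
patient	decision_cm
P1	3.5
P2	2
P3	6
P4	5.5
P5	2.5
P6	4.5
P7	7.5
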