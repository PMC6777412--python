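patient_id,recurrence,pre,mid,post,diff1,diff2,diff3
N01,0,0.78,0.70,0.67,-0.08,-0.04,-0.12
N02,0,0.68,0.64,0.69,-0.04,0.05,0.01
N03,0,0.80,0.61,0.75,-0.19,0.14,-0.05
N04,0,0.72,0.73,0.70,0.01,-0.04,-0.03
N05,0,0.80,0.64,0.70,-0.15,0.05,-0.10
N06,0,0.72,0.70,0.62,-0.01,-0.08,-0.09
N07,0,0.70,0.78,0.58,0.08,-0.20,-0.12
N08,0,0.84,0.67,0.76,-0.17,0.09,-0.09
N09,0,0.78,0.73,0.78,-0.04,0.04,0.00
N10,0,0.73,0.80,0.70,0.06,-0.10,-0.03
N11,0,0.88,0.76,0.77,-0.12,0.01,-0.11
N12,0,0.75,0.72,0.74,-0.02,0.02,0.00
N13,0,0.76,,0.72,,,-0.04
R01,1,0.68,0.66,0.76,-0.02,0.10,0.08
R02,1,0.78,0.69,0.83,-0.09,0.14,0.05
R03,1,0.67,0.71,0.78,0.04,0.07,0.11
R04,1,0.72,0.73,0.80,0.01,0.07,0.08
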