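strain,roa_24h,roa_48h,olm_48h,olm_72h
SP1,-,-,ND,ND
SP2,-,-,0.040,0.063
SP3,-,-,ND,ND
SP4,-,+,0.062,0.102
SP5,-,-,ND,ND
SP6,+,+,0.058,0.073
SP7,-,-,0.250,0.085
SP8,-,-,0.250,0.270
SP9,-,-,0.307,0.167
SP10,-,-,0.500,0.200
SP11,-,-,0.358,0.217
SP12,-,-,0.350,0.142
SP13,-,-,0.583,0.175
SP14,-,-,1.070,2.367
SP15,-,-,0.108,0.147
SP16,-,-,0.022,0.065
SP17,-,-,ND,ND
SP18,-,-,0.200,0.067
SP19,-,-,0.217,0.248
SP20,-,-,0.153,0.055
SP21,-,-,0.550,0.427
SP22,-,-,1.618,0.450
SP23,-,-,0.567,0.192
SP24,-,-,0.217,0.133
SP25,-,+,0.044,0.092
SP26,-,-,ND,ND
SP27,+,+,0.150,0.288
SP28,-,-,ND,ND
SP29,-,-,0.967,0.620
SP30,-,+,0.422,1.027
SP31,-,-,ND,ND
SP32,-,+,0.011,0.085
SP33,-,-,ND,ND
SP34,-,-,ND,ND
SP35,-,-,0.095,0.258
SP36,-,-,ND,ND
SP37,-,-,ND,ND
SP38,-,-,0.178,0.767
SP39,-,-,ND,ND
SP40,-,-,0.063,0.115
SP41,-,-,ND,ND
SP42,-,-,0.450,0.192
SP43,-,-,0.120,0.072
SP44,-,-,0.120,0.123
SP45,-,-,0.153,0.088
SP46,-,-,ND,ND
SP47,-,-,0.038,0.045
SP48,-,-,0.043,0.027
SP49,-,-,0.033,0.032
SP50,-,-,0.042,0.037
SP51,-,-,0.058,0.032
SP52,-,-,ND,ND
SP53,-,-,ND,ND
SP54,-,-,0.037,0.045
SP55,-,-,0.035,0.062
SP56,-,-,0.052,0.000
SP57,-,-,0.038,0.183
SP58,-,-,ND,ND
SP59,-,-,0.000,0.085
SP60,-,-,ND,ND
SP61,-,-,0.040,0.037
SP62,-,-,ND,ND
SP63,-,-,0.038,0.053
SP64,-,-,0.057,0.000
SP65,-,-,0.045,0.043
SP66,-,-,0.115,0.047
SP67,-,-,0.053,0.075
SP68,-,-,ND,ND
SP69,-,-,ND,ND
SP70,-,-,0.043,0.070
SP71,+,+,0.043,0.052
SP72,-,-,0.208,0.244
SP73,+,++,1.083,0.740
SP74,-,-,0.088,0.000
SP75,+,++,1.540,1.667
SP76,-,-,1.297,1.317
SP77,-,-,0.483,0.228
SP78,-,-,0.220,0.150
SP79,-,-,1.167,1.245
SP80,+,+,0.137,0.110
SP81,-,-,0.543,0.293
SP82,-,+,0.235,0.250
SP83,+,+,0.625,1.433
SP84,-,+,0.167,0.133
SP85,-,-,0.077,0.000
SP86,-,-,0.063,0.070
SP87,-,+,0.058,0.000
SP88,-,-,ND,ND
SP89,-,-,ND,ND
SP90,-,+,0.593,0.233
SP91,-,-,0.517,0.767
SP92,+,+,0.517,0.522
SP93,++,++,0.610,0.633
SP94,-,-,0.550,0.257
SP95,-,-,1.027,0.600
SP96,-,-,0.073,0.085
SP97,-,-,ND,ND
SP98,-,-,ND,ND
SP99,-,-,ND,ND
SP100,-,-,0.400,0.642
SP101,-,-,0.000,0.122
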