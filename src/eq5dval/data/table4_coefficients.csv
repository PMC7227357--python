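term,model1,model2,model3,model4
constant,-0.0299,-0.0141,,
MO2,-0.1154,-0.1292,-0.1158,-0.1340
MO3,-0.2180,-0.2058,-0.2111,-0.2159
SC2,-0.1060,-0.1329,-0.1064,-0.1377
SC3,-0.2172,-0.2220,-0.2103,-0.2321
UA2,-0.0879,-0.1170,-0.0884,-0.1218
UA3,-0.2413,-0.2103,-0.2345,-0.2205
PD2,-0.0767,-0.0673,-0.0772,-0.0721
PD3,-0.2553,-0.1967,-0.2484,-0.2068
AD2,-0.0646,-0.1096,-0.0650,-0.1145
AD3,-0.2087,-0.1893,-0.2018,-0.1994
N3,0.0439,-0.0318,,
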