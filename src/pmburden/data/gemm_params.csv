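endpoint,age_group,theta,alpha,mu,nu,counterfactual
NCD_LRI,adult_25plus,0.1430,1.6,15.5,36.8,2.4
IHD,adult_25plus,0.2969,1.9,12.0,40.2,2.4
stroke,adult_25plus,0.2720,6.2,16.7,23.7,2.4
COPD,adult_25plus,0.2510,6.5,2.5,32.0,2.4
LC,adult_25plus,0.2942,6.2,9.3,29.8,2.4
LRI,adult_25plus,0.4468,6.4,5.7,8.4,2.4
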