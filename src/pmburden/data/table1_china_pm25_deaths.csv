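scenario,year,pathway,endpoint,deaths_million
HIST,2010,linear,AD,0.37
HIST,2010,linear,CD,3.08
HIST,2010,linear,total,3.45
HIST,2010,nonlinear,LC,0.17
HIST,2010,nonlinear,COPD,0.29
HIST,2010,nonlinear,IHD,0.47
HIST,2010,nonlinear,stroke,0.15
HIST,2010,nonlinear,LRI,0.07
HIST,2010,nonlinear,total,1.75
CLE,2020,linear,AD,0.32
CLE,2020,linear,CD,2.96
CLE,2020,linear,total,3.28
CLE,2020,nonlinear,LC,0.22
CLE,2020,nonlinear,COPD,0.29
CLE,2020,nonlinear,IHD,0.60
CLE,2020,nonlinear,stroke,0.18
CLE,2020,nonlinear,LRI,0.09
CLE,2020,nonlinear,total,2.11
CLE,2030,linear,AD,0.21
CLE,2030,linear,CD,2.02
CLE,2030,linear,total,2.23
CLE,2030,nonlinear,LC,0.19
CLE,2030,nonlinear,COPD,0.26
CLE,2030,nonlinear,IHD,0.54
CLE,2030,nonlinear,stroke,0.15
CLE,2030,nonlinear,LRI,0.08
CLE,2030,nonlinear,total,1.78
CLE,2040,linear,AD,0.19
CLE,2040,linear,CD,1.87
CLE,2040,linear,total,2.06
CLE,2040,nonlinear,LC,0.22
CLE,2040,nonlinear,COPD,0.33
CLE,2040,nonlinear,IHD,0.65
CLE,2040,nonlinear,stroke,0.19
CLE,2040,nonlinear,LRI,0.10
CLE,2040,nonlinear,total,2.15
CLE,2049,linear,AD,0.18
CLE,2049,linear,CD,1.80
CLE,2049,linear,total,1.98
CLE,2049,nonlinear,LC,0.23
CLE,2049,nonlinear,COPD,0.34
CLE,2049,nonlinear,IHD,0.67
CLE,2049,nonlinear,stroke,0.19
CLE,2049,nonlinear,LRI,0.11
CLE,2049,nonlinear,total,2.23
MFR,2020,linear,AD,0.32
MFR,2020,linear,CD,2.97
MFR,2020,linear,total,3.29
MFR,2020,nonlinear,LC,0.23
MFR,2020,nonlinear,COPD,0.29
MFR,2020,nonlinear,IHD,0.60
MFR,2020,nonlinear,stroke,0.18
MFR,2020,nonlinear,LRI,0.09
MFR,2020,nonlinear,total,2.12
MFR,2030,linear,AD,0.10
MFR,2030,linear,CD,0.97
MFR,2030,linear,total,1.07
MFR,2030,nonlinear,LC,0.10
MFR,2030,nonlinear,COPD,0.14
MFR,2030,nonlinear,IHD,0.34
MFR,2030,nonlinear,stroke,0.07
MFR,2030,nonlinear,LRI,0.04
MFR,2030,nonlinear,total,1.07
MFR,2040,linear,AD,0.07
MFR,2040,linear,CD,0.71
MFR,2040,linear,total,0.78
MFR,2040,nonlinear,LC,0.09
MFR,2040,nonlinear,COPD,0.14
MFR,2040,nonlinear,IHD,0.34
MFR,2040,nonlinear,stroke,0.07
MFR,2040,nonlinear,LRI,0.04
MFR,2040,nonlinear,total,1.08
MFR,2049,linear,AD,0.06
MFR,2049,linear,CD,0.63
MFR,2049,linear,total,0.69
MFR,2049,nonlinear,LC,0.09
MFR,2049,nonlinear,COPD,0.14
MFR,2049,nonlinear,IHD,0.33
MFR,2049,nonlinear,stroke,0.06
MFR,2049,nonlinear,LRI,0.04
MFR,2049,nonlinear,total,1.05
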