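age_group,2010,2049
0–4,0.055,0.035
5–9,0.055,0.037
10–14,0.060,0.040
15–19,0.075,0.045
20–24,0.095,0.050
25–29,0.090,0.055
30–34,0.085,0.060
35–39,0.085,0.065
40–44,0.090,0.070
45–49,0.080,0.075
50–54,0.065,0.078
55–59,0.045,0.080
60–64,0.040,0.080
65–69,0.035,0.070
70–74,0.020,0.060
75–79,0.013,0.045
80–84,0.008,0.032
85+,0.004,0.023
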