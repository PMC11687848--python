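subject,sex,age_yr,mass_kg,height_m,bmi,experience_yr
1,M,60,87,1.78,27.5,7
2,F,29,65,1.70,22.5,6
3,M,64,78,1.71,26.7,46
4,M,57,80,1.80,24.7,6
5,M,47,89,1.85,26.0,9
6,M,49,91,1.80,28.1,8
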