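role,kind,family,params,time_divisor
us_tech,new,triangular,10;15;20,1
us_tech,return,triangular,10;15;20,1
check_in,new,weibull3,5;1.96;700,60
check_in,return,beta4,5;2100;1.96;14.6,60
nurse,new,loglogistic3,100;2.92;417,60
nurse,return,pearson6_4,51;1320;2.31;9.93,60
provider_A,new,pearson6_4,73;1890;5.12;10.6,60
provider_A,return,pearson6_4,8;1990;3.14;9.16,60
provider_B,new,gamma3,30;3.02;391,60
provider_B,return,loglogistic3,2;2.57;818,60
provider_C,new,weibull3,185;1.71;904,60
provider_C,return,loglogistic3,36;2.85;555,60
provider_D,new,erlang3,61;5;188,60
provider_D,return,gamma3,20;2.38;285,60
provider_E,new,loglogistic3,121;3.17;741,60
provider_E,return,pearson6_4,22;461;8.31;6.62,60
lab,new,pearson6_4,1;4950;1.57;18.5,60
lab,return,lognormal3,9;5.87;0.995,60
check_out,new,triangular,1;2;3,1
check_out,return,triangular,1;2;3,1
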