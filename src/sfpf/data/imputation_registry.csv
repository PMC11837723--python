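name,form,direction,intercept,slope,source
rice_2007,linear,sf_from_pf,64.0,0.84,"Rice TW et al. Comparison of the SpO2/FiO2 ratio and the PaO2/FiO2 ratio in patients with acute lung injury or ARDS. Chest 2007;132:410-417 (SF = 64 + 0.84 PF)"
bilan_2015,linear,sf_from_pf,57.0,0.61,"Bilan N et al. Validity of SpO2/FiO2 ratio in detection of acute lung injury and ARDS. J Cardiovasc Thorac Res 2015;7:28-31 (SF = 57 + 0.61 PF)"
severinghaus_loglinear,loglinear,pf_from_sf,-0.637149,1.055713,"synthetic reference: OLS of ln PF on ln SF over Severinghaus-curve-exact (PaO2 40-92 mmHg x FiO2 0.21-1.0) pairs with SpO2 <= 97%; derived by this package, not a literature imputation"
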