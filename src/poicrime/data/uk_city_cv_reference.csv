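city,baseline_r2_mean,baseline_r2_sd,model_r2_mean,model_r2_sd,published_improvement_pct
Bristol,0.2968,0.0476,0.6091,0.0439,105
Manchester,0.4405,0.0461,0.6443,0.0482,46
Cardiff,0.5632,0.0582,0.6729,0.0461,19
Leeds,0.6091,0.0552,0.7102,0.0500,16
Bradford,0.2681,0.0587,0.4309,0.0571,60
Birmingham,0.3754,0.0821,0.6033,0.0495,60
Sheffield,0.5220,0.0488,0.6295,0.0501,20
Liverpool,0.6825,0.0457,0.6926,0.0639,1
Leicester,0.3575,0.0354,0.6589,0.0321,84
Wakefield,0.4609,0.0787,0.5730,0.0763,24
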