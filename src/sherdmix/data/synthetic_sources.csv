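source,fatty_acid,delta_mean,delta_sd,conc_pct_fa,fa_per_dry_weight
maize,C16:0,-14.5,1.0,12.0,0.04
maize,C18:0,-16.0,1.0,2.0,0.04
maize,C18:1,-15.0,1.0,28.0,0.04
marine,C16:0,-24.0,1.2,18.0,0.15
marine,C18:0,-23.5,1.2,4.0,0.15
marine,C18:1,-24.5,1.2,12.0,0.15
C3_plant,C16:0,-30.0,1.2,15.0,0.10
C3_plant,C18:0,-31.0,1.2,3.0,0.10
C3_plant,C18:1,-30.5,1.2,35.0,0.10
ruminant,C16:0,-29.0,1.0,25.0,0.60
ruminant,C18:0,-31.0,1.0,20.0,0.60
ruminant,C18:1,-30.0,1.0,35.0,0.60
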