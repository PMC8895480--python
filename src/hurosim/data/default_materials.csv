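material,direction,breakpoint_strain,slope,units
skin,tangential,0.0,0.1,MPa
skin,tangential,0.4,18.8,MPa
soft_tissue,normal,0.0,0.08,MPa
soft_tissue,normal,0.15,0.2,MPa
soft_tissue,normal,0.3,0.6,MPa
soft_tissue,normal,0.45,5.0,MPa
padding,normal,0.0,0.5,MPa
padding,tangential,0.0,0.3,MPa
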