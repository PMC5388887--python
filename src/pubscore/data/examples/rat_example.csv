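animal_id,species,age_pnd,vo_age_pnd,follicle_class,follicle_diameters_um,follicle_health,cl_generations,oocyte_location
rat-metestrus-2nd-cycle,rat,40,33,F3,,,"gen=current,lut=partial,mit=abundant,vasc=1|gen=r1,lut=full,apo=abundant,grade=1",isthmus_nude
rat-estrus-1st-cycle,rat,36,34,F1,,,"gen=current,lut=none,mit=present,rupt=1",ampulla_coc
rat-prepubertal,rat,32,,F2,,,,none
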