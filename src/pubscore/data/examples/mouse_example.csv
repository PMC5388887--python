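animal_id,species,age_pnd,vo_age_pnd,follicle_class,follicle_diameters_um,follicle_health,cl_generations,oocyte_location
mouse-proestrus-1st-cycle,mouse,42,32,F4,,,"gen=current,lut=full,apo=abundant",none
mouse-diestrus-1st-cycle,mouse,41,33,F3,,,"gen=current,lut=full,fib=1",uterotubal_junction
mouse-prepubertal,mouse,38,,,260;320;410,healthy;healthy;atretic,,none
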