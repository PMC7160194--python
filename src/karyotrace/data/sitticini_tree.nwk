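(((Jollas_cupreus,(Attinella_concolor,Attinella_dorsata)),((Sittisax_ranieri,Sittisax_saxicola),Tomis_manabita)),((Attulus_finschi,(Attulus_pubescens,(Attulus_fasciger,Attulus_terebratus))),((Attulus_ammophilus,Attulus_burjaticus),((Attulus_cutleri,Attulus_striatus),(Attulus_caricis,(Attulus_rupicola_floricola,(Attulus_floricola,Attulus_inexpectus)))))));
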