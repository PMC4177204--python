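vaccine_name,vaccine_vo_id,n_vae
Recombivax HB,VO_0010737,20
Comvax,VO_0000028,19
Menactra,VO_0000071,18
Tetanus and Diphtheria Toxoids Adsorbed by MA Biological,VO_0000111,18
Prevnar 13,VO_0000090,16
PedvaxHIB,VO_0000083,15
RabAvert,VO_0000094,14
JE-Vax,VO_0000066,13
Tetanus Toxoid (boost only),VO_0000984,13
Tetanus Toxoid Adsorbed,VO_0000048,13
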