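vaccine_name,vaccine_vo_id,vae_location,vae_name_insert,vae_name_oae,oae_id,age_category,age_years,vae_occurrence,reference
Afluria,VO_0004810,injection-site,pain,injection-site pain AE,OAE_0000369,child,5-8,65%,Afluria package insert (FDA)
Afluria,VO_0004810,injection-site,pain,injection-site pain AE,OAE_0000369,child,9-17,55%,Afluria package insert (FDA)
Afluria,VO_0004810,injection-site,pain,injection-site pain AE,OAE_0000369,adult,18-64,60%,Afluria package insert (FDA)
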