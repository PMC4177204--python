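vaccine_name,vaccine_vo_id,vae_location,vae_name_insert,vae_name_oae,oae_id,age_category,age_years,vae_occurrence,reference
Afluria,VO_0004810,injection-site,pain,injection-site pain AE,OAE_0000369,adult,18-64,60%,Afluria package insert (FDA)
Afluria,VO_0004810,systemic,headache,headache AE,OAE_0000377,adult,18-64,26%,Afluria package insert (FDA)
Afluria,VO_0004810,systemic,fever,fever AE,OAE_0000361,child,5-17,16%,Afluria package insert (FDA)
Afluria,VO_0004810,systemic,malaise,malaise AE,OAE_0000390,adult,18-64,20%,Afluria package insert (FDA)
Afluria,VO_0004810,systemic,muscle aches,myalgia AE,OAE_0000375,adult,18-64,13%,Afluria package insert (FDA)
Afluria,VO_0004810,systemic,irritability,irritability AE,OAE_0001105,child,5-8,9%,Afluria package insert (FDA)
Afluria,VO_0004810,injection-site,swelling,local swelling AE,OAE_0001139,child,5-17,10%,Afluria package insert (FDA)
Afluria,VO_0004810,injection-site,redness,injection-site redness AE,OAE_0001546,child,5-17,17%,Afluria package insert (FDA)
Afluria,VO_0004810,systemic,tiredness,fatigue AE,OAE_0000034,adult,18-64,15%,Afluria package insert (FDA)
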