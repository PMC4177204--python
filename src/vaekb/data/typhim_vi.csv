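vaccine_name,vaccine_vo_id,vae_location,vae_name_insert,vae_name_oae,oae_id,age_category,age_years,vae_occurrence,reference
Typhim Vi,VO_0000738,injection-site,tenderness,injection-site tenderness AE,OAE_0001901,adult,18-40,97.5%,Typhim Vi package insert (FDA)
Typhim Vi,VO_0000738,systemic,headache,headache AE,OAE_0000377,adult,18-40,20.5%,Typhim Vi package insert (FDA)
Typhim Vi,VO_0000738,systemic,fever,fever AE,OAE_0000361,adult,18-40,2%,Typhim Vi package insert (FDA)
Typhim Vi,VO_0000738,systemic,malaise,malaise AE,OAE_0000390,adult,18-40,24%,Typhim Vi package insert (FDA)
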