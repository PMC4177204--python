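id,label,parent_ids,source
OAE_0000001,adverse event,,OAE
OAE_0000004,behavior and neurological AE,OAE_0000001,OAE
OAE_0000017,pain AE,OAE_0000004,OAE
OAE_0000369,injection-site pain AE,OAE_0000017,OAE
OAE_0000377,headache AE,OAE_0000017,OAE
OAE_0000375,myalgia AE,OAE_0000017,OAE
OAE_0000390,malaise AE,OAE_0000004,OAE
OAE_0000034,fatigue AE,OAE_0000004,OAE
OAE_0001105,irritability AE,OAE_0000004,OAE
OAE_0000361,fever AE,OAE_0000001,OAE
OAE_0000020,swelling AE,OAE_0000001,OAE
OAE_0001139,local swelling AE,OAE_0000020,OAE
OAE_0000021,redness AE,OAE_0000001,OAE
OAE_0001546,injection-site redness AE,OAE_0000021,OAE
OAE_0000503,erythema AE,OAE_0000001,OAE
OAE_0000644,injection-site erythema AE,OAE_0000503|OAE_0000777,OAE
OAE_0000777,injection-site adverse event,OAE_0000001,OAE
UBERON_0012338,injection site,,UBERON
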