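ae_name,oae_id,n_vaccines,percent
injection-site pain AE,OAE_0000369,43,68.3
headache AE,OAE_0000377,39,61.9
fever AE,OAE_0000361,34,54.0
local swelling AE,OAE_0001139,30,47.6
injection-site redness AE,OAE_0001546,25,40.7
irritability AE,OAE_0001105,23,36.5
malaise AE,OAE_0000390,21,33.3
injection-site erythema AE,OAE_0000644,20,31.7
myalgia AE,OAE_0000375,19,30.2
fatigue AE,OAE_0000034,18,28.6
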