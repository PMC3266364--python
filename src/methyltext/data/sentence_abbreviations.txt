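al.
et al.
Fig.
Figs.
vs.
e.g.
i.e.
Dr.
Prof.
approx.
ca.
cf.
No.
Ref.
Refs.
resp.
St.
wt.
vol.
min.
max.
sec.
inc.
spp.
subsp.
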