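# Template chain -> subunit mapping for an 18-subunit branch-junction model
# (7 Arp2/3 complex subunits + mother actins M1-M8 + daughter actins D1-D3).
# Fill in the chain ids from the deposition's chain/entity annotations, then
# remove the leading '#' from each line.  Optional third column restricts an
# entry to a residue range: "M1 A 1-375".
#ARP2  ?
#ARP3  ?
#ARPC1 ?
#ARPC2 ?
#ARPC3 ?
#ARPC4 ?
#ARPC5 ?
#M1 ?
#M2 ?
#M3 ?
#M4 ?
#M5 ?
#M6 ?
#M7 ?
#M8 ?
#D1 ?
#D2 ?
#D3 ?
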