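# Chain -> subunit mapping for the inactive Arp2/3 complex crystal structure
# (accession 1TYQ; the 1K8K crystal form uses the same chain convention).
# Based on the widely used Arp2/3 crystal-structure chain naming —
# verify against the deposition's entity annotations before use.
ARP3  A
ARP2  B
ARPC1 C
ARPC2 D
ARPC3 E
ARPC4 F
ARPC5 G
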