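# Illustrative demo registry: known domain architectures, N->C order.
# Consecutive repeats are collapsed on load (PF00008,PF00008 == PF00008).
PF00051
PF00017
PF00018
PF00046
PF00089
PF00051,PF01822
PF00051,PF00017
PF00051,PF00046
PF00008,PF00051
PF00084,PF00089
PF00018,PF00017
PF00008,PF00008,PF00084
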