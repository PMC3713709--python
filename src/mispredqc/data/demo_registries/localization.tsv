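# Illustrative demo registry: obligatory-compartment Pfam families.
# Demo data only — supply Pfam/SwissProt-derived lists for real analyses.
accession	compartment
PF00051	extracellular
PF01822	extracellular
PF00008	extracellular
PF00084	extracellular
PF00089	extracellular
PF00040	extracellular
PF00057	extracellular
PF00090	extracellular
PF00017	cytoplasmic
PF00018	cytoplasmic
PF00169	cytoplasmic
PF00595	cytoplasmic
PF00531	cytoplasmic
PF00046	nuclear
PF00096	nuclear
PF00249	nuclear
PF00505	nuclear
PF00170	nuclear
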