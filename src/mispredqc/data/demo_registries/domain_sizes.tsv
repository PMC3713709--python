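# Illustrative demo registry: reference domain lengths (residues).
# length_sd may be empty; families without it use fractional bounds.
accession	reference_length	length_sd	source_n
PF00051	80	6	200
PF01822	92	8	150
PF00008	38	4	500
PF00084	60	5	300
PF00089	220	12	400
PF00017	78	6	250
PF00018	48	4	260
PF00046	57	3	350
PF00040	49		120
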