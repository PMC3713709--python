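# mispredqc

Quality control for predicted protein sequences.

Gene prediction in intron-rich eukaryotic genomes is error-prone, and the
erroneous protein models it produces — truncated, chimeric, or stitched
from the wrong exons — contaminate public databases and distort
genome-scale analyses downstream. `mispredqc` flags such sequences by a
simple principle: **a protein whose annotated features contradict basic
cell biology is more likely a prediction error than a novelty.** It is
aimed at genome-annotation and database-curation pipelines, and at anyone
who wants a per-sequence "is this protein model believable?" check before
an evolutionary analysis.

## The eleven rules

Given a protein's domain hits (Pfam-style), membrane topology (signal
peptide, signal anchor, TM helices, GPI anchor) and the genomic placement
of its coding segments, the engine raises a conflict when:

| # | conflict |
|---|---|
| 1 | obligatory-extracellular domain(s) but no export signal (signal peptide, signal anchor or TM helix) |
| 2 | extracellular **and** cytoplasmic domains but no membrane-spanning helix |
| 3 | extracellular and nuclear domains co-occur (unconditional) |
| 4 | a domain instance's length deviates from its family reference (`\|obs − ref\| > k·SD`, default k = 2.5) |
| 5 | coding segments map to ≥ 2 chromosomes (interchromosomal chimera) |
| 6 | signal peptide + cytoplasmic domains but no membrane-spanning helix |
| 7 | GPI anchor without a secretory signal peptide |
| 8 | GPI anchor + cytoplasmic domains |
| 9 | GPI anchor + nuclear domains |
| 10 | GPI anchor + TM helices |
| 11 | domain architecture absent from the registry of known architectures |

Topology features are a consensus over predictors (SignalP + PrediSi for
signal peptides, TMHMM + Phobius for helices): present if *any* predictor
calls the feature, absent only on unanimity. Rules with missing evidence
are skipped with a reason, never silently passed. See
[docs/methods.md](docs/methods.md) for the policies and thresholds.

## Worked example

Generate a small synthetic corpus with planted errors, check it, and
summarize:

```sh
mispredqc fixtures --seed 3 --n-clean 3 --plant "1:1,4:2,5:1" --out demo
mispredqc check --fasta demo/proteins.fasta --domtblout demo/domains.domtblout \
    --signalp demo/signalp_short.txt --predisi demo/predisi.tsv \
    --tmhmm demo/tmhmm_short.txt --phobius demo/phobius.txt \
    --gpi demo/gpi.tsv --psl demo/segments.psl \
    --out demo_out --database SwissProt --species "Homo sapiens"
```

```
INFO read 7 sequences from demo/proteins.fasta
INFO rule  1 (extracellular domain(s) without export signal): 1 sequence(s)
INFO rule  4 (domain size deviation): 2 sequence(s)
INFO rule  5 (interchromosomal chimeric protein): 1 sequence(s)
INFO 4 of 7 sequences flagged
INFO reports written to demo_out
```

Each flagged row in `demo_out/reports.tsv` names the violated rule and
its evidence — e.g. the planted truncated-domain record reads:

```
MP00005  4  domain size deviation  PF01822.14 (WSC) at 131-169: observed 39 residues vs 92±2.5·8
```

meaning a WSC-family hit of 39 residues against a family reference of
92 ± 8, outside the 2.5-SD band — the signature of a truncated gene
model. `demo_out/reports.json` holds the full three-section report per
protein (input info, feature annotations, conclusions).
`mispredqc stats demo_out/reports.json` then aggregates:

```
database   species       n_total  n_flagged  percentage
SwissProt  Homo sapiens  7        4          57.14
```

(57.14 % because this demo corpus is mostly planted errors; real
databases are a few percent.)

The same machinery is available as a library:

```python
from mispredqc import evaluate, load_registries, demo_registry_dir
report = evaluate(record, load_registries(demo_registry_dir()))
report.rule_ids   # e.g. {4}
```

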