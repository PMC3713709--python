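# Methods

## The consistency model

`mispredqc` treats a predicted protein sequence as a claim that must be
internally consistent with basic cell biology. Three kinds of evidence are
merged into one record per protein:

* **Domain hits** — Pfam-style HMM matches with protein and HMM
  coordinates, bit score and independent E-value.
* **Membrane topology** — secretory signal peptide, signal anchor,
  transmembrane (TM) helices and GPI anchor, each as a consensus over the
  per-predictor calls (SignalP + PrediSi for signal peptides, TMHMM +
  Phobius for helices, a DGPI-style caller for GPI anchors).
* **Genomic segment mappings** — the best placement of each coding
  segment from translated BLAT alignments (PSL).

Eleven rules check these claims against each other. Rules 1–3 and 6–10
are pure boolean logic over compartment-exclusive domains (obligatory
extracellular / cytoplasmic / nuclear Pfam families) and topology
features; rule 4 compares each domain instance's length with its family
reference; rule 5 checks that all coding segments map to one chromosome;
rule 11 looks the protein's domain architecture up in a registry of
known architectures. A violated rule yields a conflict with evidence; a
rule whose inputs are missing (no predictor output of a required kind, no
genome mappings, no domain hits for the architecture rule) is *skipped
with a reason*, never silently passed — an important distinction for a QC
tool, since "no evidence of error" and "no evidence" are different claims.

## Consensus policy

A topology feature is PRESENT if **any** configured predictor calls it and
ABSENT only when every predictor that was run agrees it is absent
(`consensus_mode: any`, the default; `majority` is available). The span of
a present feature is the union of the supporting spans. The rationale is
asymmetry of cost: most rules flag errors on the *absence* of a signal, so
demanding unanimous absence is the conservative choice — a single
predictor seeing a signal peptide is enough to withhold a "missing signal
peptide" verdict.

Signal anchors need one extra step. The upstream tools do not label them:
TMHMM and Phobius report an uncleaved N-terminal anchor as an ordinary TM
helix. When no cleaved signal peptide is called, the first consensus helix
starting within the N-terminal window (`sp_tm_overlap_window`, default
45 residues) is therefore reclassified as the signal anchor and removed
from the helix list. Explicit anchor votes (e.g. from a pre-annotated
JSON corpus) take precedence over this derivation.

### Effective TM helices

Rules 2, 6 and 10 must not fire on predictor artifacts, so they count
*effective* helices: a helix overlapping the signal peptide/anchor within
the first 45 residues is the export signal itself, and on GPI-anchored
proteins a helix lying entirely within the C-terminal window
(`gpi_cterm_window`, default 40 residues) is the transient GPI-attachment
signal; both are excluded. Rule 1, by contrast, counts raw predictor-level
helices — even a reclassified helix proves the chain reaches the membrane.

A consequence worth knowing: a type-II membrane protein whose only helix
is its signal anchor has zero effective helices, so extracellular +
cytoplasmic domains on such a protein trigger rule 2. This is the
documented reading of "must contain transmembrane helices" as requiring a
membrane-passing segment beyond the export signal.

## Rule 4 (domain size deviation)

For each hit whose family is in the size registry, the observed length is
`ali_end − ali_start + 1`. With a recorded length SD the instance is
flagged when `|observed − reference| > k·SD` (default `k = 2.5`; SD = 0
means the family length is fixed). Without an SD, symmetric fractional
bounds are used: flag when `observed/reference` falls outside
`[c, 2−c]` with `c = size_rule_min_hmm_coverage = 0.70`. Both knobs live
in `EngineConfig` and are printed in the conflict evidence. The exact
statistic behind the original tool is not published, so this criterion is
this package's own, deliberately simple and auditable.

## Rule interdependence: why rule 8 never fires alone

Rule 8 (GPI + cytoplasmic domain) requires a GPI anchor and a cytoplasmic
domain. If the signal peptide is absent, rule 7 fires; if present and no
effective helix exists, rule 6 fires; if an effective helix exists,
rule 10 fires. The three cases are exhaustive, so a record violating
rule 8 always violates at least one other rule. The fixture generator
refuses a single-rule plant for 8 and offers the multi-conflict mode
(`planted_multi=(((6, 8), n),)`) instead. The same logic makes the
combination {extracellular + nuclear + GPI, no signal peptide} resolve to
{1, 3, 7, 9}: a GPI call is not an export signal, so rule 1 fires too.

## Parsers and thresholds

Each parser targets one dialect and fails loudly on others: HMMER3
`domtblout` (hmmscan orientation), SignalP 4 short, a PrediSi-like table,
TMHMM 2 short, Phobius feature-table output, a simple GPI table, and PSL.
Defaults, all configurable:

| parameter | default | role |
|---|---|---|
| `e_value_max` | 1e-3 | domain-hit acceptance (independent E-value); permissive enough to keep the truncated hits rule 4 needs |
| same-family overlap merge | >50 % of the shorter hit | split alignments of one domain instance collapse to the lower-E hit |
| `min_identity` | 0.95 | PSL alignment identity, `matches/(matches+mismatches)` |
| `min_coverage` | 0.80 | aligned query fraction; one top-scoring alignment kept per segment |
| `size_rule_k` | 2.5 | rule 4 SD multiplier |
| `size_rule_min_hmm_coverage` | 0.70 | rule 4 fractional bounds without SD |
| `sp_tm_overlap_window` | 45 | N-terminal reclassification window (residues) |
| `gpi_cterm_window` | 40 | C-terminal GPI-signal window (residues) |

Percentages in corpus statistics are rounded half-up to two decimals,
matching the precision convention of published database summaries.

## Synthetic corpora

The fixture generator emulates exactly what the rules read: feature
placement, not sequence realism. Sequences are uniform draws over the 20
standard residues with a methionine start; domain positions, signal
peptide lengths (18–28), helix placements and GPI omega sites are drawn
from ranges wide enough to vary but constrained so each planted record
violates its planted rule set and nothing else — verified against the
engine at generation time, so a generator/engine disagreement is an error,
not a silent bad fixture. Clean records rotate through four templates
(secreted two-domain, cytoplasmic, nuclear, single-pass membrane protein).
Default corpus composition is what the tests and acceptance script use:
3–5 clean records plus one record per plantable rule, sequence lengths
350–450 residues.

Mock predictor files are emitted from the records and parsed back; the
round trip is exact by construction. PSL lines are rendered with a fixed
query size of 1000, which makes the stored identity/coverage fractions
reconstruct to integer match counts exactly. What passing these tests
shows is that the parsers, consensus policy and rules compose correctly;
it says nothing about upstream predictor accuracy on real sequences —
fixtures contain no false predictor calls, no disagreeing predictors
(except where planted), and no alignment noise.

## Registries

The bundled demo registries are illustrative: a handful of well-known
compartment-exclusive families (e.g. Kringle and WSC as extracellular,
SH2/SH3 as cytoplasmic, homeodomain as nuclear), hand-set reference
lengths, and the architectures the fixtures need. They make the pipeline
runnable and testable offline; any real corpus analysis must supply
registries derived from curated Pfam/SwissProt annotation, in the three
documented TSV schemas. Disjointness of the three compartment sets is
enforced at load — "obligatory" localization implies exclusivity.

## Numerical and tie-break choices

* Coordinates are 1-based inclusive everywhere; parsers convert at the
  boundary (PSL's half-open 0-based query coords become fractions only).
* Pfam version suffixes are kept for display, stripped for every lookup.
* Architecture comparison is exact ordered-tuple membership after
  version-stripping and (by default) consecutive-repeat collapsing; no
  clan-level grouping is attempted.
* Equal-score PSL alignments keep the first seen; domain hits merge
  toward the lower E-value.
* `compute_flag_percentage` uses decimal half-up rounding, so 0.125 %
  prints as 0.13, not the banker's 0.12.

## Limitations

* Rules 2 and 6 check helix *presence*, not whether a helix lies between
  the conflicting domains; topology-order checking is a non-goal.
* CDD/RPS-BLAST domain input is not parsed; the pipeline standardizes on
  Pfam-style hits.
* The tool flags sequences; it never corrects them, and it assigns no
  error probability.
* Selenocysteine and ambiguity codes are accepted with a warning; the
  upstream predictors' behaviour on such residues is their own affair.
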