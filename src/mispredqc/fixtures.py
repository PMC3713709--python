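"""Deterministic synthetic corpora with planted annotation conflicts.

The generator builds protein records whose features violate exactly one
chosen consistency rule (or a chosen combination, in multi-conflict
mode), plus clean records that violate none.  Every record is assembled
through the same consensus path the real pipeline uses and verified
against the rule engine at generation time, so the planted conflict set
is guaranteed, not hoped for.

:func:`emit_mock_tool_outputs` serializes a corpus into the upstream
tools' file dialects (FASTA, domtblout, SignalP/TMHMM/Phobius short
outputs, a GPI table and PSL), and :func:`load_mock_tool_outputs` parses
them back; the round trip reproduces the records field for field, which
is what makes the parsers testable without running any external tool.

Sequences are drawn from a uniform residue model with a methionine
start; the rules never read residue identities beyond the alphabet
check, so no further realism is attempted.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .engine import DEFAULT_CONFIG, EngineConfig, evaluate
from .model import (
    ConflictReport,
    DomainHit,
    ProteinRecord,
    SegmentMapping,
)
from .parsers import (
    RawPredictorCall,
    assemble_records,
    read_domtblout,
    read_fasta,
    read_fasta_descriptions,
    read_gpi_table,
    read_phobius_short,
    read_predisi_table,
    read_psl,
    read_signalp_short,
    read_tmhmm_short,
)
from .registries import Registries, demo_registry_dir, load_registries

__all__ = [
    "FixtureGenerationError",
    "FixtureSpec",
    "generate_corpus",
    "emit_mock_tool_outputs",
    "load_mock_tool_outputs",
    "MOCK_FILES",
]

ANALYSIS_DATE = "2024-01-01"
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# families drawn from the bundled demo registries
EXTRA_A = ("PF00051.10", "Kringle", 80)
EXTRA_B = ("PF01822.14", "WSC", 92)
CYTO_A = ("PF00017", "SH2", 78)
NUCLEAR_A = ("PF00046", "Homeodomain", 57)

MOCK_FILES = {
    "fasta": "proteins.fasta",
    "domtblout": "domains.domtblout",
    "signalp": "signalp_short.txt",
    "predisi": "predisi.tsv",
    "tmhmm": "tmhmm_short.txt",
    "phobius": "phobius.txt",
    "gpi": "gpi.tsv",
    "psl": "segments.psl",
    "meta": "meta.json",
}


class FixtureGenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: clean records plus per-rule planted conflicts.

    ``planted`` lists ``(rule_id, count)`` pairs for single-rule plants;
    ``planted_multi`` is the documented multi-conflict mode and lists
    ``(rule_id_tuple, count)`` pairs for records engineered to violate a
    specific combination of rules (needed e.g. for rule 8, which cannot
    occur alone: a GPI anchor with cytoplasmic domains entails either a
    missing signal peptide, a membrane helix, or the signal-peptide/
    cytoplasmic conflict of rule 6).
    """

    seed: int
    n_clean: int = 5
    planted: tuple[tuple[int, int], ...] = ()
    planted_multi: tuple[tuple[tuple[int, ...], int], ...] = ()
    sequence_length_range: tuple[int, int] = (350, 450)
    registry_profile: str = "demo"
    species: str = "synthetic metazoan"
    include_mappings: bool = True

    def __post_init__(self) -> None:
        if self.n_clean < 0:
            raise ValueError("n_clean must be >= 0")
        for rule_id, count in self.planted:
            if count < 0:
                raise ValueError("planted counts must be >= 0")
            if rule_id not in range(1, 12):
                raise ValueError(f"unknown rule id {rule_id}")
        if self.sequence_length_range[0] < 50:
            raise ValueError("minimum sequence length must be >= 50")


# ---------------------------------------------------------------------------
# Record construction


@dataclass
class _Plan:
    """Feature layout for one record before assembly."""

    sp_end: Optional[int] = None
    helices: list[tuple[int, int]] = field(default_factory=list)
    gpi_omega: Optional[int] = None
    hits: list[tuple[str, str, int, int]] = field(default_factory=list)  # acc, name, start, length
    chromosomes: list[str] = field(default_factory=list)
    expected_rules: frozenset[int] = frozenset()


def _near(rng: random.Random, ref: int) -> int:
    return ref + rng.randint(-1, 1)


def _layout_domains(
    rng: random.Random, fams: list[tuple[str, str, int]], lengths: list[int],
    first_start: int,
) -> list[tuple[str, str, int, int]]:
    hits = []
    cursor = first_start
    for (acc, name, _), length in zip(fams, lengths):
        start = cursor + rng.randint(4, 14)
        hits.append((acc, name, start, length))
        cursor = start + length - 1
    return hits


def _plan_record(
    rng: random.Random, rules: frozenset[int], length: int
) -> _Plan:
    """Lay out features violating exactly ``rules`` (empty set = clean)."""
    p = _Plan(expected_rules=rules)
    sp_end = rng.randint(18, 28)
    mid_helix = (rng.randint(150, 190), 0)
    mid_helix = (mid_helix[0], mid_helix[0] + 22)

    def domains(fams, lengths=None):
        if lengths is None:
            lengths = [_near(rng, ref) for _, _, ref in fams]
        p.hits = _layout_domains(rng, fams, lengths, first_start=max(36, (p.sp_end or 0) + 8))

    if rules == frozenset():
        template = rng.randrange(4)
        if template == 0:  # secreted two-domain protein
            p.sp_end = sp_end
            domains([EXTRA_A, EXTRA_B])
        elif template == 1:  # cytoplasmic protein
            domains([CYTO_A])
        elif template == 2:  # nuclear protein
            domains([NUCLEAR_A])
        else:  # single-pass membrane protein, extra + cyto sides
            p.sp_end = sp_end
            domains([EXTRA_A, CYTO_A])
            p.helices = [mid_helix]
    elif rules == {1}:
        domains([EXTRA_A])
    elif rules == {2}:
        # N-terminal helix is the (derived) signal anchor, so no
        # membrane-spanning helix remains between the compartments
        h0 = rng.randint(5, 15)
        p.helices = [(h0, h0 + 22)]
        domains([EXTRA_A, CYTO_A])
    elif rules == {3}:
        p.sp_end = sp_end
        domains([EXTRA_A, NUCLEAR_A])
    elif rules == {4}:
        p.sp_end = sp_end
        domains([EXTRA_A, EXTRA_B], lengths=[_near(rng, 80), rng.randint(35, 45)])
    elif rules == {5}:
        p.sp_end = sp_end
        domains([EXTRA_A])
        p.chromosomes = ["chr3", "chr7"]
    elif rules == {6}:
        p.sp_end = sp_end
        domains([CYTO_A])
    elif rules == {7}:
        p.gpi_omega = length - rng.randint(8, 16)
    elif rules == {8}:
        raise FixtureGenerationError(
            "rule 8 cannot be violated in isolation (a GPI anchor with "
            "cytoplasmic domains always also violates rule 6, 7 or 10); "
            "use planted_multi, e.g. ((6, 8), n)"
        )
    elif rules == {9}:
        p.sp_end = sp_end
        p.gpi_omega = length - rng.randint(8, 16)
        domains([NUCLEAR_A])
    elif rules == {10}:
        p.sp_end = sp_end
        p.gpi_omega = length - rng.randint(8, 16)
        p.helices = [mid_helix]
    elif rules == {11}:
        p.sp_end = sp_end
        domains([EXTRA_B, EXTRA_A])  # order absent from the demo registry
    elif rules == {6, 8}:
        p.sp_end = sp_end
        p.gpi_omega = length - rng.randint(8, 16)
        domains([CYTO_A])
    elif rules == {1, 3, 7, 9}:
        # a GPI call is not an export signal, so an unexported
        # extracellular domain also violates rule 1 here
        p.gpi_omega = length - rng.randint(8, 16)
        domains([EXTRA_A, NUCLEAR_A])
    else:
        raise FixtureGenerationError(
            f"no construction template for rule combination {sorted(rules)}"
        )
    if not p.chromosomes:
        p.chromosomes = [rng.choice(["chr1", "chr2", "chr3", "chr5", "chrX"])]
    return p


def _plan_to_inputs(
    rng: random.Random, pid: str, plan: _Plan, length: int, include_mappings: bool
) -> tuple[str, list[DomainHit], list[RawPredictorCall], list[SegmentMapping]]:
    seq = "M" + "".join(rng.choice(RESIDUES) for _ in range(length - 1))

    hits = []
    per_family_count: dict[str, int] = {}
    for acc, name, start, dlen in plan.hits:
        fam = acc.split(".")[0]
        per_family_count[fam] = per_family_count.get(fam, 0) + 1
        e_value = float(f"{rng.randint(10, 95) / 10:.1f}e-{rng.randint(8, 28)}")
        score = float(f"{rng.uniform(35.0, 140.0):.1f}")
        hits.append(
            DomainHit(
                family_acc=acc,
                family_name=name,
                copy_index=per_family_count[fam],
                ali_start=start,
                ali_end=start + dlen - 1,
                hmm_start=1,
                hmm_end=dlen,
                score=score,
                e_value=e_value,
            )
        )

    calls: list[RawPredictorCall] = []
    sp_called = plan.sp_end is not None
    sp_span = (1, plan.sp_end) if sp_called else None
    calls.append(RawPredictorCall("SignalP", pid, "signal_peptide", sp_called, sp_span,
                                  score=0.85 if sp_called else 0.12))
    calls.append(RawPredictorCall("PrediSi", pid, "signal_peptide", sp_called, sp_span,
                                  score=0.91 if sp_called else 0.07))
    if plan.helices:
        for span in plan.helices:
            calls.append(RawPredictorCall("TMHMM", pid, "tm_helix", True, span))
        for span in plan.helices:
            calls.append(RawPredictorCall("Phobius", pid, "tm_helix", True, span))
    else:
        calls.append(RawPredictorCall("TMHMM", pid, "tm_helix", False))
        calls.append(RawPredictorCall("Phobius", pid, "tm_helix", False))
    # Phobius reports cleaved signal peptides too (its FT SIGNAL rows)
    calls.append(RawPredictorCall("Phobius", pid, "signal_peptide", sp_called, sp_span))
    gpi_called = plan.gpi_omega is not None
    calls.append(
        RawPredictorCall("DGPI", pid, "gpi_anchor", gpi_called,
                         (plan.gpi_omega, plan.gpi_omega) if gpi_called else None)
    )

    mappings = []
    if include_mappings:
        chroms = plan.chromosomes
        for seg in range(1, 3):
            chrom = chroms[(seg - 1) % len(chroms)]
            aligned = rng.randint(940, 1000)
            mismatches = rng.randint(0, 18)
            matches = aligned - mismatches
            mappings.append(
                SegmentMapping(
                    segment_index=seg,
                    chromosome=chrom,
                    strand=rng.choice("+-"),
                    identity=matches / aligned,
                    query_coverage=aligned / 1000,
                    alignment_score=float(matches - mismatches),
                )
            )
    return seq, hits, calls, mappings


def generate_corpus(
    spec: FixtureSpec,
    registries: Optional[Registries] = None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> tuple[list[ProteinRecord], list[ConflictReport]]:
    """Generate records plus the reports the engine must produce on them.

    Each planted record is evaluated at generation time; if its conflict
    set differs from the planted rule set, generation fails rather than
    returning a corpus with wrong expectations.  The same seed yields a
    byte-identical corpus.
    """
    if registries is None:
        registries = load_registries(demo_registry_dir())
    lo, hi = spec.sequence_length_range
    if lo < 300:
        raise FixtureGenerationError(
            "sequence_length_range minimum below 300 leaves no room to "
            "place domains and topology features"
        )
    wanted: list[frozenset[int]] = [frozenset()] * spec.n_clean
    for rule_id, count in spec.planted:
        if rule_id == 5 and count > 0 and not spec.include_mappings:
            raise FixtureGenerationError(
                "cannot plant rule 5 with include_mappings=False"
            )
        wanted += [frozenset({rule_id})] * count
    for combo, count in spec.planted_multi:
        wanted += [frozenset(combo)] * count

    rng = random.Random(spec.seed)
    records: list[ProteinRecord] = []
    reports: list[ConflictReport] = []
    fasta_entries = []
    all_hits: dict[str, list[DomainHit]] = {}
    all_calls: list[RawPredictorCall] = []
    all_maps: dict[str, list[SegmentMapping]] = {}
    descriptions: dict[str, str] = {}
    alt_ids: dict[str, list[tuple[str, str]]] = {}

    for idx, rules in enumerate(wanted, start=1):
        pid = f"MP{idx:05d}"
        length = rng.randint(lo, hi)
        plan = _plan_record(rng, rules, length)
        seq, hits, calls, mappings = _plan_to_inputs(
            rng, pid, plan, length, spec.include_mappings
        )
        fasta_entries.append((pid, seq))
        if hits:
            all_hits[pid] = hits
        all_calls.extend(calls)
        if mappings:
            all_maps[pid] = mappings
        label = "clean" if not rules else "conflict " + ",".join(map(str, sorted(rules)))
        descriptions[pid] = f"synthetic {label} protein"
        alt_ids[pid] = [("RefSeq", f"XP_{rng.randint(0, 99999999):08d}.1")]

    records = assemble_records(
        fasta_entries, all_hits, all_calls, all_maps,
        species=spec.species, descriptions=descriptions, alt_ids=alt_ids,
        analysis_date=ANALYSIS_DATE, config=config,
    )
    for record, rules in zip(records, wanted):
        report = evaluate(record, registries, config)
        if report.rule_ids != rules:
            raise FixtureGenerationError(
                f"{record.protein_id}: planted rules {sorted(rules)} but "
                f"engine found {sorted(report.rule_ids)}"
            )
        reports.append(report)
    return records, reports


# ---------------------------------------------------------------------------
# Mock tool-output emission


def emit_mock_tool_outputs(records: list[ProteinRecord], out_dir) -> dict[str, Path]:
    """Write a complete mock input set consistent with ``records``.

    Parsing the emitted files with :func:`load_mock_tool_outputs`
    reproduces the records exactly.  Records whose signal anchor came
    from an explicit anchor vote cannot be expressed in the TMHMM/
    Phobius dialects and are rejected.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {key: out / name for key, name in MOCK_FILES.items()}

    fasta_lines = []
    dom_lines = [
        "#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target",
    ]
    sp_lines = ["# SignalP-4.1   short format",
                "# name                     Cmax  pos  Ymax  pos  Smax  pos  Smean   D     ?  Dmaxcut    Networks-used"]
    predisi_lines = ["# PrediSi signal peptide predictions",
                     "# id\tscore\tdecision\tcleavage_pos"]
    tm_lines = []
    phob_lines = []
    gpi_lines = ["# GPI anchor predictions", "# id\tdecision\tomega_site"]
    psl_lines = []

    for rec in records:
        topo = rec.topology
        if topo.signal_anchor is not None and topo.predictor_votes.get("signal_anchor"):
            raise ValueError(
                f"{rec.protein_id}: explicit signal-anchor votes have no "
                f"mock file dialect"
            )
        fasta_lines.append(f">{rec.protein_id} {rec.description}".rstrip())
        seq = rec.sequence
        fasta_lines += [seq[i:i + 60] for i in range(0, len(seq), 60)]

        fam_totals: dict[str, int] = {}
        for hit in rec.domain_hits:
            fam = hit.family_acc.split(".")[0]
            fam_totals[fam] = fam_totals.get(fam, 0) + 1
        for hit in rec.domain_hits:
            fam = hit.family_acc.split(".")[0]
            dom_lines.append(
                f"{hit.family_name:<20} {hit.family_acc:<11} {hit.hmm_end:4d} "
                f"{rec.protein_id:<20} -          {len(seq):5d} "
                f"{hit.e_value:9.1e} {hit.score:6.1f}   0.1 "
                f"{hit.copy_index:3d} {fam_totals[fam]:3d} "
                f"{hit.e_value:9.1e} {hit.e_value:9.1e} {hit.score:6.1f}   0.1 "
                f"{hit.hmm_start:5d} {hit.hmm_end:5d} "
                f"{hit.ali_start:5d} {hit.ali_end:5d} "
                f"{hit.ali_start:5d} {hit.ali_end:5d} 0.95 {hit.family_name} domain"
            )

        sp = topo.signal_peptide
        if sp is not None:
            sp_lines.append(
                f"{rec.protein_id:<24} 0.52  {sp.end + 1:3d}  0.68  {sp.end + 1:3d}  "
                f"0.89  {sp.end:3d}  0.74  0.850  Y  0.450    SignalP-noTM"
            )
            predisi_lines.append(f"{rec.protein_id}\t0.910\tY\t{sp.end}")
        else:
            sp_lines.append(
                f"{rec.protein_id:<24} 0.11    2  0.10    2  "
                f"0.12    1  0.09  0.120  N  0.450    SignalP-noTM"
            )
            predisi_lines.append(f"{rec.protein_id}\t0.070\tN\t0")

        # an anchor without explicit votes was derived from a helix call:
        # re-emit it as the leading TMHMM/Phobius helix
        helices = list(topo.tm_helices)
        if topo.signal_anchor is not None:
            helices = [topo.signal_anchor] + helices
        topo_str, side = "", "o"
        for a, b in helices:
            topo_str += f"{side}{a}-{b}"
            side = "i" if side == "o" else "o"
        topo_str += side
        tm_lines.append(
            f"{rec.protein_id}\tlen={len(seq)}\tExpAA={22.5 * len(helices):.2f}\t"
            f"First60=0.00\tPredHel={len(helices)}\tTopology={topo_str}"
        )

        phob_lines.append(f"ID   {rec.protein_id}")
        if sp is not None:
            phob_lines.append(f"FT   SIGNAL    {sp.start:6d} {sp.end:6d}")
        for a, b in helices:
            phob_lines.append(f"FT   TRANSMEM  {a:6d} {b:6d}")
        phob_lines.append("//")

        if topo.gpi_anchor is not None:
            gpi_lines.append(f"{rec.protein_id}\tY\t{topo.gpi_anchor}")
        else:
            gpi_lines.append(f"{rec.protein_id}\tN\t-")

        for m in rec.segment_mappings:
            q_size = 1000
            q_end = round(m.query_coverage * q_size)
            matches = round(m.identity * q_end)
            mismatches = q_end - matches
            if float(matches - mismatches) != m.alignment_score:
                raise ValueError(
                    f"{rec.protein_id} segment {m.segment_index}: mapping "
                    f"not representable with unit query size 1000"
                )
            t_start = 5000 + 10000 * m.segment_index
            psl_lines.append(
                "\t".join(
                    str(v)
                    for v in [
                        matches, mismatches, 0, 0, 0, 0, 0, 0, m.strand,
                        f"{rec.protein_id}_seg{m.segment_index}",
                        q_size, 0, q_end,
                        m.chromosome, 50000000, t_start, t_start + q_end,
                        1, f"{q_end},", "0,", f"{t_start},",
                    ]
                )
            )

    meta = {
        "species": records[0].species if records else "",
        "analysis_date": records[0].analysis_date if records else "",
        "alt_ids": {r.protein_id: [list(p) for p in r.alt_ids] for r in records},
    }

    paths["fasta"].write_text("\n".join(fasta_lines) + "\n")
    paths["domtblout"].write_text("\n".join(dom_lines) + "\n")
    paths["signalp"].write_text("\n".join(sp_lines) + "\n")
    paths["predisi"].write_text("\n".join(predisi_lines) + "\n")
    paths["tmhmm"].write_text("\n".join(tm_lines) + "\n")
    paths["phobius"].write_text("\n".join(phob_lines) + "\n")
    paths["gpi"].write_text("\n".join(gpi_lines) + "\n")
    paths["psl"].write_text("\n".join(psl_lines) + ("\n" if psl_lines else ""))
    paths["meta"].write_text(json.dumps(meta, indent=1, sort_keys=True))
    return paths


def load_mock_tool_outputs(
    in_dir,
    config: EngineConfig = DEFAULT_CONFIG,
    e_value_max: float = 1e-3,
    min_identity: float = 0.95,
    min_coverage: float = 0.80,
) -> list[ProteinRecord]:
    """Parse a mock input set back into records (inverse of emission)."""
    d = Path(in_dir)
    paths = {key: d / name for key, name in MOCK_FILES.items()}
    fasta = read_fasta(paths["fasta"])
    descriptions = read_fasta_descriptions(paths["fasta"])
    hits = read_domtblout(paths["domtblout"], e_value_max=e_value_max)
    calls = (
        read_signalp_short(paths["signalp"])
        + read_predisi_table(paths["predisi"])
        + read_tmhmm_short(paths["tmhmm"])
        + read_phobius_short(paths["phobius"])
        + read_gpi_table(paths["gpi"])
    )
    maps = read_psl(paths["psl"], min_identity=min_identity, min_coverage=min_coverage)
    meta = json.loads(paths["meta"].read_text()) if paths["meta"].exists() else {}
    return assemble_records(
        fasta, hits, calls, maps,
        species=meta.get("species", ""),
        descriptions=descriptions,
        alt_ids={
            pid: [tuple(p) for p in pairs]
            for pid, pairs in meta.get("alt_ids", {}).items()
        },
        analysis_date=meta.get("analysis_date", ""),
        config=config,
    )
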