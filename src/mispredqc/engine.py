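"""The eleven annotation-consistency rules and their supporting policies.

The premise: a predicted protein whose features contradict basic cell
biology — an extracellular domain with no way to reach the extracellular
space, a "protein" whose exons sit on two chromosomes, a domain far
shorter than its family ever is — is more likely a gene-prediction error
than a genuine novelty.  Each rule checks one such contradiction:

1.  extracellular domain(s) but no export signal (signal peptide, signal
    anchor or transmembrane helix)
2.  extracellular and cytoplasmic domains but no transmembrane helix
3.  co-occurrence of extracellular and nuclear domains
4.  domain size deviation (truncated or inflated domain instance)
5.  interchromosomal chimeric protein
6.  secretory signal peptide with cytoplasmic domains but no
    transmembrane helix
7.  GPI anchor without a secretory signal peptide
8.  GPI anchor co-occurring with cytoplasmic domains
9.  GPI anchor co-occurring with nuclear domains
10. GPI anchor co-occurring with transmembrane helices
11. domain architecture absent from the registry of known architectures

A rule raises a conflict; it never edits the record.  Rules whose
evidence is missing (no genome mappings, no predictor output for a
required feature kind) are skipped and reported as such rather than
silently passed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import yaml

from .model import (
    Conflict,
    ConflictReport,
    ProteinRecord,
    SignalPeptide,
    TopologyFeatures,
    strip_version,
)
from .registries import (
    ArchitectureRegistry,
    LocalizationRegistry,
    Registries,
    SizeRegistry,
    collapse_repeats,
)

__all__ = [
    "RULE_NAMES",
    "ALL_RULES",
    "EngineConfig",
    "consensus_topology",
    "effective_tm_helices",
    "evaluate",
    "evaluate_corpus",
    "compute_flag_percentage",
]

RULE_NAMES: dict[int, str] = {
    1: "extracellular domain(s) without export signal",
    2: "extracellular and cytoplasmic domains without transmembrane helix",
    3: "co-occurrence of extracellular and nuclear domains",
    4: "domain size deviation",
    5: "interchromosomal chimeric protein",
    6: "signal peptide with cytoplasmic domains without transmembrane helix",
    7: "GPI anchor without secretory signal peptide",
    8: "co-occurrence of GPI anchor and cytoplasmic domains",
    9: "co-occurrence of GPI anchor and nuclear domains",
    10: "co-occurrence of GPI anchor and transmembrane helix",
    11: "domain architecture deviation",
}

ALL_RULES: frozenset[int] = frozenset(RULE_NAMES)


@dataclass(frozen=True)
class EngineConfig:
    """Tunable thresholds of the rule engine.

    consensus_mode
        ``any`` (default): a topology feature is present if any predictor
        calls it, absent only if every configured predictor agrees it is
        absent.  ``majority``: present if strictly more predictors call it
        than not.
    size_rule_k
        Number of standard deviations around the reference length within
        which a domain instance is considered normal (rule 4).
    size_rule_min_hmm_coverage
        When a family has no length SD on record, an instance is flagged
        if observed/reference falls below this fraction or above its
        mirror ``2 - fraction``.
    sp_tm_overlap_window
        N-terminal window (residues) within which a predicted helix that
        overlaps the signal peptide/anchor is treated as the export
        signal itself rather than a membrane-spanning segment.
    gpi_cterm_window
        C-terminal window (residues) within which a helix on a
        GPI-anchored protein is treated as the GPI-attachment signal.
    """

    consensus_mode: str = "any"
    size_rule_k: float = 2.5
    size_rule_min_hmm_coverage: float = 0.70
    sp_tm_overlap_window: int = 45
    gpi_cterm_window: int = 40
    repeat_collapse: bool = True
    enabled_rules: frozenset[int] = ALL_RULES

    def __post_init__(self) -> None:
        if self.consensus_mode not in {"any", "majority"}:
            raise ValueError(f"unknown consensus_mode {self.consensus_mode!r}")
        if self.sp_tm_overlap_window <= 0 or self.gpi_cterm_window <= 0:
            raise ValueError("reclassification windows must be positive")
        if self.size_rule_k < 0:
            raise ValueError("size_rule_k must be >= 0")
        if not (0 < self.size_rule_min_hmm_coverage <= 1):
            raise ValueError("size_rule_min_hmm_coverage must be in (0, 1]")
        bad = set(self.enabled_rules) - ALL_RULES
        if bad:
            raise ValueError(f"unknown rule ids {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "EngineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "enabled_rules" in raw:
            raw["enabled_rules"] = frozenset(int(r) for r in raw["enabled_rules"])
        return cls(**raw)


DEFAULT_CONFIG = EngineConfig()


# ---------------------------------------------------------------------------
# Consensus topology


def _feature_present(votes: list[tuple[str, bool]], mode: str) -> bool:
    if not votes:
        return False
    # aggregate per predictor first: a predictor calling two helices is
    # still one voice, not two
    by_pred: dict[str, bool] = {}
    for name, called in votes:
        by_pred[name] = by_pred.get(name, False) or called
    yes = sum(by_pred.values())
    if mode == "majority":
        return yes > len(by_pred) - yes
    return yes > 0


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent spans into sorted non-overlapping ones."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def consensus_topology(
    votes: dict[str, list[tuple[str, bool, Optional[tuple[int, int]]]]],
    config: EngineConfig = DEFAULT_CONFIG,
) -> TopologyFeatures:
    """Combine per-predictor feature calls into one consensus topology.

    ``votes`` maps a feature kind to ``(predictor, called, span)`` triples.
    Under the default policy a feature is PRESENT if any predictor calls
    it (span = union of the supporting spans) and ABSENT only when every
    predictor that was run agrees it is absent.

    Signal anchors are rarely labelled explicitly by the upstream tools:
    TMHMM and Phobius report an uncleaved N-terminal anchor as a plain
    transmembrane helix.  When no cleaved signal peptide is called and no
    explicit anchor vote exists, the first consensus helix starting
    within ``sp_tm_overlap_window`` is therefore reclassified as the
    signal anchor and removed from the helix list.
    """
    plain = {
        kind: [(name, called) for name, called, _ in vv]
        for kind, vv in votes.items()
    }
    mode = config.consensus_mode

    sp = None
    sp_votes = votes.get("signal_peptide", [])
    if _feature_present(plain.get("signal_peptide", []), mode):
        spans = [span for _, called, span in sp_votes if called and span]
        end = max(e for _, e in spans)
        sp = SignalPeptide(start=1, end=end, cleavage_site=end)

    helices: list[tuple[int, int]] = []
    if _feature_present(plain.get("tm_helix", []), mode):
        spans = [span for _, called, span in votes["tm_helix"] if called and span]
        helices = _merge_spans(spans)

    anchor = None
    if _feature_present(plain.get("signal_anchor", []), mode):
        spans = [
            span for _, called, span in votes["signal_anchor"] if called and span
        ]
        anchor = (min(s for s, _ in spans), max(e for _, e in spans))
    elif sp is None and helices and helices[0][0] <= config.sp_tm_overlap_window:
        anchor = helices[0]
        helices = helices[1:]

    gpi = None
    if _feature_present(plain.get("gpi_anchor", []), mode):
        sites = [span[0] for _, called, span in votes["gpi_anchor"] if called and span]
        gpi = max(sites)

    return TopologyFeatures(
        signal_peptide=sp,
        signal_anchor=anchor,
        tm_helices=helices,
        gpi_anchor=gpi,
        predictor_votes=plain,
    )


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def effective_tm_helices(
    record: ProteinRecord, config: EngineConfig = DEFAULT_CONFIG
) -> list[tuple[int, int]]:
    """Helices that plausibly span a membrane, after signal reclassification.

    A helix overlapping the consensus signal peptide/anchor inside the
    N-terminal window is the export signal itself (it still satisfies the
    export requirement of rule 1 but is excluded from the helix counts of
    rules 2, 6 and 10).  On GPI-anchored proteins, helices lying entirely
    within the C-terminal window are the transient GPI-attachment signal
    and are likewise excluded.
    """
    topo = record.topology
    export_span = None
    if topo.signal_peptide is not None:
        export_span = (topo.signal_peptide.start, topo.signal_peptide.end)
    elif topo.signal_anchor is not None:
        export_span = topo.signal_anchor

    n = len(record)
    cterm_start = n - config.gpi_cterm_window + 1
    out = []
    for helix in topo.tm_helices:
        if (
            export_span is not None
            and helix[0] <= config.sp_tm_overlap_window
            and _overlaps(helix, export_span)
        ):
            continue
        if topo.gpi_anchor is not None and helix[0] >= cterm_start:
            continue
        out.append(helix)
    return out


# ---------------------------------------------------------------------------
# Individual rules.  Each returns a Conflict or None.


def _hits_in(record: ProteinRecord, families: frozenset[str]) -> list:
    return [h for h in record.domain_hits if strip_version(h.family_acc) in families]


def _hit_ev(hit) -> str:
    return f"{hit.family_acc} ({hit.family_name}) at {hit.ali_start}-{hit.ali_end}"


def rule1_extracellular_without_export(
    record: ProteinRecord, loc: LocalizationRegistry
) -> Optional[Conflict]:
    """Obligatory-extracellular domains demand an export signal.

    Raw predictor-level helices count as export signals here: even a
    helix later reclassified as a signal anchor proves the chain can
    reach the membrane.
    """
    extra = _hits_in(record, loc.extracellular)
    if not extra:
        return None
    topo = record.topology
    has_export = (
        topo.signal_peptide is not None
        or topo.signal_anchor is not None
        or bool(topo.tm_helices)
        or topo.raw_tm_called()
    )
    if has_export:
        return None
    return Conflict(
        rule_id=1,
        message=RULE_NAMES[1],
        evidence=tuple(_hit_ev(h) for h in extra)
        + ("no signal peptide, signal anchor or transmembrane helix",),
    )


def rule2_extra_cyto_without_tm(
    record: ProteinRecord, loc: LocalizationRegistry,
    config: EngineConfig = DEFAULT_CONFIG,
) -> Optional[Conflict]:
    extra = _hits_in(record, loc.extracellular)
    cyto = _hits_in(record, loc.cytoplasmic)
    if extra and cyto and not effective_tm_helices(record, config):
        return Conflict(
            rule_id=2,
            message=RULE_NAMES[2],
            evidence=tuple(_hit_ev(h) for h in extra + cyto)
            + ("no membrane-spanning helix",),
        )
    return None


def rule3_extra_nuclear_cooccur(
    record: ProteinRecord, loc: LocalizationRegistry
) -> Optional[Conflict]:
    # unconditional: no membrane topology rescues this combination
    extra = _hits_in(record, loc.extracellular)
    nuc = _hits_in(record, loc.nuclear)
    if extra and nuc:
        return Conflict(
            rule_id=3,
            message=RULE_NAMES[3],
            evidence=tuple(_hit_ev(h) for h in extra + nuc),
        )
    return None


def rule4_domain_size_deviation(
    record: ProteinRecord, sizes: SizeRegistry,
    config: EngineConfig = DEFAULT_CONFIG,
) -> Optional[Conflict]:
    """Flag domain instances whose length falls outside the family range.

    With a recorded SD the bound is ``|observed - reference| > k * SD``;
    without one, symmetric fractional bounds around the reference length
    are used.  SD = 0 means the family length is fixed.
    """
    evidence = []
    for hit in record.domain_hits:
        entry = sizes.get(hit.family_acc)
        if entry is None:
            continue
        obs = hit.length
        ref = entry.reference_length
        if entry.length_sd is not None:
            deviant = abs(obs - ref) > config.size_rule_k * entry.length_sd
            bound = f"{ref}±{config.size_rule_k:g}·{entry.length_sd:g}"
        else:
            lo = config.size_rule_min_hmm_coverage
            ratio = obs / ref
            deviant = ratio < lo or ratio > 2 - lo
            bound = f"[{lo:g}, {2 - lo:g}]·{ref}"
        if deviant:
            evidence.append(f"{_hit_ev(hit)}: observed {obs} residues vs {bound}")
    if evidence:
        return Conflict(rule_id=4, message=RULE_NAMES[4], evidence=tuple(evidence))
    return None


def rule5_interchromosomal_chimera(record: ProteinRecord) -> Optional[Conflict]:
    chroms = {m.chromosome for m in record.segment_mappings}
    if len(chroms) >= 2:
        ev = tuple(
            f"segment {m.segment_index} -> {m.chromosome} "
            f"(identity {m.identity:.3f})"
            for m in record.segment_mappings
        )
        return Conflict(rule_id=5, message=RULE_NAMES[5], evidence=ev)
    return None


def rule6_sp_cyto_without_tm(
    record: ProteinRecord, loc: LocalizationRegistry,
    config: EngineConfig = DEFAULT_CONFIG,
) -> Optional[Conflict]:
    cyto = _hits_in(record, loc.cytoplasmic)
    if (
        record.topology.signal_peptide is not None
        and cyto
        and not effective_tm_helices(record, config)
    ):
        sp = record.topology.signal_peptide
        return Conflict(
            rule_id=6,
            message=RULE_NAMES[6],
            evidence=(f"signal peptide 1-{sp.end}",)
            + tuple(_hit_ev(h) for h in cyto),
        )
    return None


def rule7_gpi_without_sp(record: ProteinRecord) -> Optional[Conflict]:
    topo = record.topology
    if topo.gpi_anchor is not None and topo.signal_peptide is None:
        return Conflict(
            rule_id=7,
            message=RULE_NAMES[7],
            evidence=(f"GPI omega site at {topo.gpi_anchor}, no signal peptide",),
        )
    return None


def rule8_gpi_with_cyto(
    record: ProteinRecord, loc: LocalizationRegistry
) -> Optional[Conflict]:
    cyto = _hits_in(record, loc.cytoplasmic)
    if record.topology.gpi_anchor is not None and cyto:
        return Conflict(
            rule_id=8, message=RULE_NAMES[8],
            evidence=tuple(_hit_ev(h) for h in cyto),
        )
    return None


def rule9_gpi_with_nuclear(
    record: ProteinRecord, loc: LocalizationRegistry
) -> Optional[Conflict]:
    nuc = _hits_in(record, loc.nuclear)
    if record.topology.gpi_anchor is not None and nuc:
        return Conflict(
            rule_id=9, message=RULE_NAMES[9],
            evidence=tuple(_hit_ev(h) for h in nuc),
        )
    return None


def rule10_gpi_with_tm(
    record: ProteinRecord, config: EngineConfig = DEFAULT_CONFIG
) -> Optional[Conflict]:
    if record.topology.gpi_anchor is None:
        return None
    helices = effective_tm_helices(record, config)
    if helices:
        ev = tuple(f"helix {s}-{e}" for s, e in helices)
        return Conflict(rule_id=10, message=RULE_NAMES[10], evidence=ev)
    return None


def architecture_key(
    record: ProteinRecord, repeat_collapse: bool = True
) -> tuple[str, ...]:
    """N->C ordered, version-stripped family tuple of a record."""
    accs = [
        strip_version(h.family_acc)
        for h in sorted(record.domain_hits, key=lambda h: (h.ali_start, h.ali_end))
    ]
    if repeat_collapse:
        accs = collapse_repeats(accs)
    return tuple(accs)


def rule11_architecture_deviation(
    record: ProteinRecord, archs: ArchitectureRegistry,
    config: EngineConfig = DEFAULT_CONFIG,
) -> Optional[Conflict]:
    key = architecture_key(record, config.repeat_collapse)
    if key and key not in archs:
        return Conflict(
            rule_id=11,
            message=RULE_NAMES[11],
            evidence=("architecture " + ",".join(key) + " not among known architectures",),
        )
    return None


# ---------------------------------------------------------------------------
# Orchestration


def evaluate(
    record: ProteinRecord,
    registries: Registries,
    config: EngineConfig = DEFAULT_CONFIG,
) -> ConflictReport:
    """Run every enabled rule on one record.

    All conflicts are collected (not first-hit).  A rule whose required
    evidence is absent — no predictor output for a feature kind it needs,
    no genome mappings, no domain hits for the architecture rule — is
    recorded in ``skipped`` with the reason rather than passed silently.
    """
    topo = record.topology
    loc = registries.localization

    # which feature kinds each topology-dependent rule needs evidence for
    needs: dict[int, tuple[str, ...]] = {
        1: ("signal_peptide", "tm_helix"),
        2: ("tm_helix",),
        6: ("signal_peptide", "tm_helix"),
        7: ("gpi_anchor", "signal_peptide"),
        8: ("gpi_anchor",),
        9: ("gpi_anchor",),
        10: ("gpi_anchor", "tm_helix"),
    }

    conflicts: list[Conflict] = []
    skipped: list[tuple[int, str]] = []

    def missing_kinds(rule_id: int) -> list[str]:
        return [k for k in needs.get(rule_id, ()) if not topo.has_votes(k)]

    runners = {
        1: lambda: rule1_extracellular_without_export(record, loc),
        2: lambda: rule2_extra_cyto_without_tm(record, loc, config),
        3: lambda: rule3_extra_nuclear_cooccur(record, loc),
        4: lambda: rule4_domain_size_deviation(record, registries.sizes, config),
        5: lambda: rule5_interchromosomal_chimera(record),
        6: lambda: rule6_sp_cyto_without_tm(record, loc, config),
        7: lambda: rule7_gpi_without_sp(record),
        8: lambda: rule8_gpi_with_cyto(record, loc),
        9: lambda: rule9_gpi_with_nuclear(record, loc),
        10: lambda: rule10_gpi_with_tm(record, config),
        11: lambda: rule11_architecture_deviation(
            record, registries.architectures, config
        ),
    }

    for rule_id in sorted(config.enabled_rules):
        miss = missing_kinds(rule_id)
        if miss:
            skipped.append(
                (rule_id, "insufficient evidence: no predictions for "
                 + ", ".join(miss))
            )
            continue
        if rule_id == 5 and not record.segment_mappings:
            skipped.append((5, "insufficient evidence: no genome mappings"))
            continue
        if rule_id == 11 and not record.domain_hits:
            skipped.append((11, "no domain hits: architecture undefined"))
            continue
        conflict = runners[rule_id]()
        if conflict is not None:
            conflicts.append(conflict)

    return ConflictReport(
        protein_id=record.protein_id, conflicts=conflicts, skipped=skipped
    )


def evaluate_corpus(
    records: list[ProteinRecord],
    registries: Registries,
    config: EngineConfig = DEFAULT_CONFIG,
) -> list[ConflictReport]:
    return [evaluate(r, registries, config) for r in records]


def compute_flag_percentage(n_total: int, n_flagged: int) -> float:
    """Percentage of flagged sequences, half-up rounded to 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_flagged <= n_total):
        raise ValueError("n_flagged must satisfy 0 <= n_flagged <= n_total")
    pct = Decimal(100) * Decimal(n_flagged) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
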