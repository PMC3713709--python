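"""Typed data model shared by all stages of the pipeline.

A :class:`ProteinRecord` holds one protein sequence together with every
feature annotation the rule engine consumes: Pfam-style domain hits,
membrane-topology features (signal peptide, signal anchor, transmembrane
helices, GPI anchor) with per-predictor provenance, and genomic segment
mappings from translated alignments of the coding exons.

Coordinates are 1-based and inclusive everywhere in this package; parsers
convert from each file format's native convention at the boundary.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

__all__ = [
    "AMINO_ACID_ALPHABET",
    "PFAM_ACC_RE",
    "ValidationError",
    "DomainHit",
    "SignalPeptide",
    "TopologyFeatures",
    "SegmentMapping",
    "Conflict",
    "ConflictReport",
    "ProteinRecord",
    "strip_version",
    "validate_record",
    "records_to_json",
    "records_from_json",
    "reports_to_tsv",
]

# 20 standard residues plus ambiguity codes (X, B, Z) and selenocysteine (U).
AMINO_ACID_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU")

PFAM_ACC_RE = re.compile(r"^PF\d{5}(\.\d+)?$")

X_RUN_WARNING_LENGTH = 10


class ValidationError(ValueError):
    """A record violates a hard structural invariant."""


def strip_version(accession: str) -> str:
    """Drop a Pfam version suffix: ``PF01822.14`` -> ``PF01822``.

    Family identity is version-independent, so all registry lookups and
    architecture comparisons use the bare accession; the suffix is kept
    on the hit itself for display.
    """
    return accession.split(".", 1)[0]


@dataclass(frozen=True)
class DomainHit:
    """One Pfam-style domain match on a protein.

    ``ali_start``/``ali_end`` are residue positions on the protein,
    1-based inclusive; ``hmm_start``/``hmm_end`` are the matched span of
    the family HMM.  ``copy_index`` numbers repeated hits of the same
    family in N->C order (1 for the first copy).
    """

    family_acc: str
    family_name: str
    copy_index: int
    ali_start: int
    ali_end: int
    hmm_start: int
    hmm_end: int
    model_tag: str = "ls"
    score: float = 0.0
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if not PFAM_ACC_RE.match(self.family_acc):
            raise ValidationError(
                f"family_acc {self.family_acc!r} is not a Pfam-style accession"
            )
        if not (1 <= self.ali_start <= self.ali_end):
            raise ValidationError(
                f"{self.family_acc}: alignment span "
                f"({self.ali_start}, {self.ali_end}) is not 1 <= start <= end"
            )
        if not (1 <= self.hmm_start <= self.hmm_end):
            raise ValidationError(
                f"{self.family_acc}: HMM span "
                f"({self.hmm_start}, {self.hmm_end}) is not 1 <= start <= end"
            )
        if self.e_value < 0:
            raise ValidationError(f"{self.family_acc}: negative E-value")
        if self.copy_index < 1:
            raise ValidationError(f"{self.family_acc}: copy_index must be >= 1")

    @property
    def length(self) -> int:
        """Observed domain length in residues."""
        return self.ali_end - self.ali_start + 1


@dataclass(frozen=True)
class SignalPeptide:
    start: int
    end: int
    cleavage_site: int  # last residue of the signal; mature chain starts at +1


@dataclass
class TopologyFeatures:
    """Consensus membrane-topology features plus per-predictor votes.

    ``predictor_votes`` maps a feature kind (``signal_peptide``,
    ``signal_anchor``, ``tm_helix``, ``gpi_anchor``) to the list of
    ``(predictor_name, called)`` votes that produced the consensus, so
    the consensus policy stays auditable and re-derivable.
    """

    signal_peptide: Optional[SignalPeptide] = None
    signal_anchor: Optional[tuple[int, int]] = None
    tm_helices: list[tuple[int, int]] = field(default_factory=list)
    gpi_anchor: Optional[int] = None  # omega-site residue position
    predictor_votes: dict[str, list[tuple[str, bool]]] = field(default_factory=dict)

    def has_votes(self, kind: str) -> bool:
        return bool(self.predictor_votes.get(kind))

    def raw_tm_called(self) -> bool:
        """Whether any transmembrane predictor called >= 1 helix."""
        return any(called for _, called in self.predictor_votes.get("tm_helix", []))


@dataclass(frozen=True)
class SegmentMapping:
    """Best genomic placement of one coding segment of the protein."""

    segment_index: int
    chromosome: str
    strand: str
    identity: float
    query_coverage: float
    alignment_score: float

    def __post_init__(self) -> None:
        if self.segment_index < 1:
            raise ValidationError("segment_index must be >= 1")
        if not (0.0 <= self.identity <= 1.0):
            raise ValidationError(f"identity {self.identity} outside [0, 1]")
        if not (0.0 <= self.query_coverage <= 1.0):
            raise ValidationError(
                f"query_coverage {self.query_coverage} outside [0, 1]"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class Conflict:
    rule_id: int
    message: str
    evidence: tuple[str, ...] = ()


@dataclass
class ConflictReport:
    """Outcome of running the consistency rules on one protein.

    ``skipped`` lists ``(rule_id, reason)`` pairs for rules that could not
    be evaluated for lack of evidence (e.g. no genome mappings supplied).
    """

    protein_id: str
    conflicts: list[Conflict] = field(default_factory=list)
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = [c.rule_id for c in self.conflicts]
        if len(seen) != len(set(seen)):
            raise ValidationError(
                f"{self.protein_id}: duplicate rule ids in conflict report"
            )

    @property
    def clean(self) -> bool:
        return not self.conflicts

    @property
    def rule_ids(self) -> frozenset[int]:
        return frozenset(c.rule_id for c in self.conflicts)


@dataclass
class ProteinRecord:
    protein_id: str
    sequence: str
    alt_ids: list[tuple[str, str]] = field(default_factory=list)
    species: str = ""
    description: str = ""
    domain_hits: list[DomainHit] = field(default_factory=list)
    topology: TopologyFeatures = field(default_factory=TopologyFeatures)
    segment_mappings: list[SegmentMapping] = field(default_factory=list)
    analysis_date: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Validation


def validate_record(record: ProteinRecord) -> list[str]:
    """Check hard invariants, returning soft warnings.

    Raises :class:`ValidationError` on structural violations (bad alphabet,
    out-of-range coordinates, unsorted/overlapping helices, a signal peptide
    not anchored at residue 1).  Returns a list of non-fatal warnings: long
    runs of X, a non-methionine start (possible N-terminal truncation),
    unusual residues (U/B/Z) and entirely missing feature annotations.
    """
    warnings: list[str] = []
    seq = record.sequence
    if not seq:
        raise ValidationError(f"{record.protein_id}: empty sequence")
    bad = set(seq) - AMINO_ACID_ALPHABET
    if bad:
        raise ValidationError(
            f"{record.protein_id}: sequence contains invalid residues "
            f"{sorted(bad)} (field: sequence)"
        )
    n = len(seq)

    for hit in record.domain_hits:
        if hit.ali_end > n:
            raise ValidationError(
                f"{record.protein_id}: {hit.family_acc} alignment end "
                f"{hit.ali_end} exceeds sequence length {n} (field: domain_hits)"
            )

    topo = record.topology
    sp = topo.signal_peptide
    if sp is not None:
        if sp.start != 1:
            raise ValidationError(
                f"{record.protein_id}: signal peptide must start at residue 1, "
                f"starts at {sp.start} (field: topology.signal_peptide)"
            )
        if sp.end > n:
            raise ValidationError(
                f"{record.protein_id}: signal peptide end {sp.end} exceeds "
                f"sequence length {n}"
            )
        if not _has_supporting_vote(topo, "signal_peptide"):
            raise ValidationError(
                f"{record.protein_id}: consensus signal peptide has no "
                f"supporting predictor vote"
            )
    prev_end = 0
    for start, end in topo.tm_helices:
        if start <= prev_end:
            raise ValidationError(
                f"{record.protein_id}: transmembrane helices overlap or are "
                f"unsorted at ({start}, {end}) (field: topology.tm_helices)"
            )
        if end > n or start < 1:
            raise ValidationError(
                f"{record.protein_id}: helix ({start}, {end}) outside "
                f"sequence of length {n}"
            )
        prev_end = end
    if topo.tm_helices and not topo.raw_tm_called():
        raise ValidationError(
            f"{record.protein_id}: consensus helices have no supporting "
            f"predictor vote"
        )
    if topo.signal_anchor is not None:
        # a signal anchor may be derived from a TM-predictor helix call
        if not (
            _has_supporting_vote(topo, "signal_anchor")
            or topo.raw_tm_called()
        ):
            raise ValidationError(
                f"{record.protein_id}: consensus signal anchor has no "
                f"supporting predictor vote"
            )
    if topo.gpi_anchor is not None:
        if not _has_supporting_vote(topo, "gpi_anchor"):
            raise ValidationError(
                f"{record.protein_id}: consensus GPI anchor has no "
                f"supporting predictor vote"
            )
        if not (1 <= topo.gpi_anchor <= n):
            raise ValidationError(
                f"{record.protein_id}: GPI omega site {topo.gpi_anchor} "
                f"outside sequence of length {n}"
            )

    # soft warnings -------------------------------------------------------
    longest_x = max((len(m.group()) for m in re.finditer(r"X+", seq)), default=0)
    if longest_x >= X_RUN_WARNING_LENGTH:
        warnings.append(
            f"long X run ({longest_x} residues): possible masked or unknown region"
        )
    if seq[0] != "M":
        warnings.append(
            "sequence does not start with methionine: possible N-terminal truncation"
        )
    unusual = set(seq) & set("UBZ")
    if unusual:
        warnings.append(
            f"unusual residues present ({''.join(sorted(unusual))}): "
            f"upstream predictor fidelity not guaranteed"
        )
    if (
        not record.domain_hits
        and not record.segment_mappings
        and not topo.predictor_votes
    ):
        warnings.append("record carries no feature annotations of any kind")
    return warnings


def _has_supporting_vote(topo: TopologyFeatures, kind: str) -> bool:
    return any(called for _, called in topo.predictor_votes.get(kind, []))


# ---------------------------------------------------------------------------
# Serialization: canonical JSON corpus and a flat TSV for spreadsheets.


def _record_to_dict(record: ProteinRecord) -> dict:
    d = asdict(record)
    d["topology"]["predictor_votes"] = {
        kind: [[name, called] for name, called in votes]
        for kind, votes in record.topology.predictor_votes.items()
    }
    return d


def _record_from_dict(d: dict) -> ProteinRecord:
    topo_d = d.get("topology", {})
    sp = topo_d.get("signal_peptide")
    topology = TopologyFeatures(
        signal_peptide=SignalPeptide(**sp) if sp else None,
        signal_anchor=tuple(topo_d["signal_anchor"])
        if topo_d.get("signal_anchor")
        else None,
        tm_helices=[tuple(h) for h in topo_d.get("tm_helices", [])],
        gpi_anchor=topo_d.get("gpi_anchor"),
        predictor_votes={
            kind: [(name, bool(called)) for name, called in votes]
            for kind, votes in topo_d.get("predictor_votes", {}).items()
        },
    )
    return ProteinRecord(
        protein_id=d["protein_id"],
        sequence=d["sequence"],
        alt_ids=[tuple(pair) for pair in d.get("alt_ids", [])],
        species=d.get("species", ""),
        description=d.get("description", ""),
        domain_hits=[DomainHit(**h) for h in d.get("domain_hits", [])],
        topology=topology,
        segment_mappings=[SegmentMapping(**m) for m in d.get("segment_mappings", [])],
        analysis_date=d.get("analysis_date", ""),
    )


def records_to_json(records: Iterable[ProteinRecord]) -> str:
    """Serialize a corpus to the canonical JSON document."""
    doc = {"format": "mispredqc-records", "version": 1,
           "records": [_record_to_dict(r) for r in records]}
    return json.dumps(doc, indent=1, sort_keys=True)


def records_from_json(text: str) -> list[ProteinRecord]:
    doc = json.loads(text)
    if doc.get("format") != "mispredqc-records":
        raise ValidationError("not a mispredqc record document")
    return [_record_from_dict(d) for d in doc["records"]]


def reports_to_tsv(reports: Iterable[ConflictReport]) -> str:
    """One row per (protein, conflict); clean proteins get a single '-' row."""
    lines = ["protein_id\trule_id\tconflict\tevidence"]
    for rep in reports:
        if rep.clean:
            lines.append(f"{rep.protein_id}\t-\tclean\t-")
        else:
            for c in rep.conflicts:
                ev = "; ".join(c.evidence) if c.evidence else "-"
                lines.append(f"{rep.protein_id}\t{c.rule_id}\t{c.message}\t{ev}")
    return "\n".join(lines) + "\n"
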