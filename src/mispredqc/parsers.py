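"""Readers for the upstream tool outputs and record assembly.

Each parser targets one documented dialect and fails loudly on anything
else rather than guessing:

* FASTA (protein sequences)
* HMMER3 ``--domtblout`` per-domain table (``hmmscan`` orientation:
  target = Pfam family, query = protein)
* SignalP 4 "short" output
* A simple PrediSi-like signal-peptide table
* TMHMM 2 "short" (one line per protein, ``PredHel=``/``Topology=``)
* Phobius feature-table output (``ID``/``FT``/``//`` blocks)
* A simple GPI-anchor table (DGPI-like calls with an omega site)
* BLAT PSL for translated alignments of coding segments

All coordinates are converted to 1-based inclusive at this boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from .engine import DEFAULT_CONFIG, EngineConfig, consensus_topology
from .model import DomainHit, ProteinRecord, SegmentMapping

__all__ = [
    "ParseError",
    "RawPredictorCall",
    "read_fasta",
    "read_domtblout",
    "read_signalp_short",
    "read_predisi_table",
    "read_tmhmm_short",
    "read_phobius_short",
    "read_gpi_table",
    "read_psl",
    "assemble_records",
]

logger = logging.getLogger("mispredqc")

DEFAULT_EVALUE_MAX = 1e-3
DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MIN_COVERAGE = 0.80

FEATURE_KINDS = ("signal_peptide", "signal_anchor", "tm_helix", "gpi_anchor")


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class RawPredictorCall:
    """One predictor's verdict on one feature of one protein."""

    predictor_name: str
    protein_id: str
    feature_kind: str
    called: bool
    span: Optional[tuple[int, int]] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ParseError(f"unknown feature kind {self.feature_kind!r}")
        if self.called and self.span is None:
            raise ParseError(
                f"{self.predictor_name}/{self.protein_id}: a positive "
                f"{self.feature_kind} call requires a span"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Return ``(protein_id, uppercased sequence)`` pairs."""
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for {rec.id!r}")
        seen.add(rec.id)
        entries.append((rec.id, seq))
    return entries


def read_fasta_descriptions(path) -> dict[str, str]:
    """Description line remainders keyed by id (assembly metadata)."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out[rec.id] = desc
    return out


# ---------------------------------------------------------------------------
# HMMER3 domtblout

_DOMTBL_NCOL = 23  # 22 fixed columns + free-text description


def read_domtblout(
    path, e_value_max: float = DEFAULT_EVALUE_MAX
) -> dict[str, list[DomainHit]]:
    """Parse hmmscan ``--domtblout``, filter and number the hits.

    Keeps hits with independent (i-)E-value <= ``e_value_max``.  Hits of
    the same family overlapping each other by more than half of the
    shorter hit are merged, keeping the lower-E-value hit's coordinates,
    to avoid double-counting split alignments of one domain instance.
    ``copy_index`` numbers surviving hits per family in N->C order.
    """
    raw: dict[str, list[DomainHit]] = {}
    for lineno, line in enumerate(_lines(path), start=1):
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split(None, _DOMTBL_NCOL - 1)
        if len(cols) < _DOMTBL_NCOL - 1:  # description may be empty
            raise ParseError(
                f"{path}:{lineno}: expected >= {_DOMTBL_NCOL - 1} columns "
                f"in domtblout line, got {len(cols)}"
            )
        try:
            family_name, family_acc = cols[0], cols[1]
            protein_id = cols[3]
            i_evalue = float(cols[12])
            score = float(cols[13])
            hmm_start, hmm_end = int(cols[15]), int(cols[16])
            ali_start, ali_end = int(cols[17]), int(cols[18])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if i_evalue > e_value_max:
            continue
        hit = DomainHit(
            family_acc=family_acc,
            family_name=family_name,
            copy_index=1,
            ali_start=ali_start,
            ali_end=ali_end,
            hmm_start=hmm_start,
            hmm_end=hmm_end,
            score=score,
            e_value=i_evalue,
        )
        raw.setdefault(protein_id, []).append(hit)
    return {pid: _dedupe_and_number(hits) for pid, hits in raw.items()}


def _dedupe_and_number(hits: list[DomainHit]) -> list[DomainHit]:
    from .model import strip_version
    from dataclasses import replace

    kept: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: h.e_value):
        merged = False
        for other in kept:
            if strip_version(other.family_acc) != strip_version(hit.family_acc):
                continue
            ov = min(hit.ali_end, other.ali_end) - max(hit.ali_start, other.ali_start) + 1
            shorter = min(hit.length, other.length)
            if ov > 0.5 * shorter:
                merged = True  # keep the lower-E hit already in `kept`
                break
        if not merged:
            kept.append(hit)
    kept.sort(key=lambda h: (h.ali_start, h.ali_end))
    counter: dict[str, int] = {}
    out = []
    for hit in kept:
        fam = strip_version(hit.family_acc)
        counter[fam] = counter.get(fam, 0) + 1
        out.append(replace(hit, copy_index=counter[fam]))
    return out


# ---------------------------------------------------------------------------
# SignalP 4 short format

_SIGNALP_HEADER_HINT = "# SignalP"


def read_signalp_short(path) -> list[RawPredictorCall]:
    """SignalP 4 short output.

    Columns: ``name Cmax pos Ymax pos Smax pos Smean D ? Dmaxcut
    Networks-used``; the ``?`` column is the Y/N decision and the Ymax
    position is the first residue of the mature chain, so a YES call at
    Ymax position 23 means a signal peptide spanning residues 1-22.
    """
    lines = _lines(path)
    _require_header(lines, _SIGNALP_HEADER_HINT, path,
                    expected="'# SignalP-4.x short format' comment header")
    calls = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split()
        if len(cols) < 12:
            raise ParseError(
                f"{path}:{lineno}: expected 12 whitespace-separated columns"
            )
        name, ymax_pos, d_score, decision = cols[0], int(cols[4]), float(cols[8]), cols[9]
        called = decision == "Y"
        calls.append(
            RawPredictorCall(
                predictor_name="SignalP",
                protein_id=name,
                feature_kind="signal_peptide",
                called=called,
                span=(1, ymax_pos - 1) if called else None,
                score=d_score,
            )
        )
    return calls


def read_predisi_table(path) -> list[RawPredictorCall]:
    """PrediSi-like table: ``id  score  Y/N  cleavage_pos`` where
    cleavage_pos is the last residue of the signal peptide."""
    lines = _lines(path)
    _require_header(lines, "# PrediSi", path,
                    expected="'# PrediSi' comment header")
    calls = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split()
        if len(cols) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        name, score, decision, cleav = cols[0], float(cols[1]), cols[2], int(cols[3])
        called = decision == "Y"
        calls.append(
            RawPredictorCall(
                predictor_name="PrediSi",
                protein_id=name,
                feature_kind="signal_peptide",
                called=called,
                span=(1, cleav) if called else None,
                score=score,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# TMHMM 2 short format

_TMHMM_RE = re.compile(r"(\d+)-(\d+)")


def read_tmhmm_short(path) -> list[RawPredictorCall]:
    """TMHMM 2 one-line-per-protein output; helix spans are taken from
    the ``Topology=`` string (e.g. ``o200-222i`` -> helix 200-222)."""
    calls = []
    for lineno, line in enumerate(_lines(path), start=1):
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split()
        fields = dict(c.split("=", 1) for c in cols[1:] if "=" in c)
        if "PredHel" not in fields or "Topology" not in fields:
            raise ParseError(
                f"{path}:{lineno}: not TMHMM short format (expected "
                f"'id len=.. ExpAA=.. First60=.. PredHel=.. Topology=..')"
            )
        name = cols[0]
        n_hel = int(fields["PredHel"])
        spans = [
            (int(a), int(b)) for a, b in _TMHMM_RE.findall(fields["Topology"])
        ]
        if len(spans) != n_hel:
            raise ParseError(
                f"{path}:{lineno}: PredHel={n_hel} but topology string "
                f"contains {len(spans)} helices"
            )
        if not spans:
            calls.append(
                RawPredictorCall("TMHMM", name, "tm_helix", called=False)
            )
        for span in spans:
            calls.append(
                RawPredictorCall("TMHMM", name, "tm_helix", called=True, span=span)
            )
    return calls


# ---------------------------------------------------------------------------
# Phobius feature-table output


def read_phobius_short(path) -> list[RawPredictorCall]:
    """Phobius feature-table output: ``ID`` lines start a protein block,
    ``FT SIGNAL s e`` rows give a cleaved signal peptide, ``FT TRANSMEM
    s e`` rows give helices, ``//`` closes the block.  A block without
    SIGNAL/TRANSMEM rows yields explicit negative votes."""
    calls: list[RawPredictorCall] = []
    current: Optional[str] = None
    saw: dict[str, bool] = {}

    def close_block() -> None:
        if current is None:
            return
        if not saw.get("signal_peptide"):
            calls.append(
                RawPredictorCall("Phobius", current, "signal_peptide", called=False)
            )
        if not saw.get("tm_helix"):
            calls.append(
                RawPredictorCall("Phobius", current, "tm_helix", called=False)
            )

    for lineno, line in enumerate(_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if line.startswith("ID"):
            close_block()
            current = line.split()[1]
            saw = {}
        elif line.startswith("FT"):
            if current is None:
                raise ParseError(f"{path}:{lineno}: FT row before any ID row")
            cols = line.split()
            kind = cols[1]
            if kind in {"SIGNAL", "TRANSMEM"}:
                span = (int(cols[2]), int(cols[3]))
                fk = "signal_peptide" if kind == "SIGNAL" else "tm_helix"
                saw[fk] = True
                calls.append(
                    RawPredictorCall("Phobius", current, fk, called=True, span=span)
                )
            # other FT rows (N-REGION etc.) carry no feature of interest
        elif line.startswith("//"):
            close_block()
            current = None
        else:
            raise ParseError(
                f"{path}:{lineno}: not Phobius feature-table format "
                f"(expected ID/FT/'//' lines)"
            )
    close_block()
    return calls


# ---------------------------------------------------------------------------
# GPI table


def read_gpi_table(path) -> list[RawPredictorCall]:
    """Simple GPI-anchor table: ``id  Y/N  omega_site`` (omega is '-'
    for negative calls)."""
    lines = _lines(path)
    _require_header(lines, "# GPI", path, expected="'# GPI' comment header")
    calls = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split()
        if len(cols) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns (id, Y/N, omega)")
        name, decision, omega = cols[0], cols[1], cols[2]
        called = decision == "Y"
        span = (int(omega), int(omega)) if called else None
        calls.append(
            RawPredictorCall("DGPI", name, "gpi_anchor", called=called, span=span)
        )
    return calls


# ---------------------------------------------------------------------------
# BLAT PSL

_PSL_MIN_COLS = 21


def read_psl(
    path,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> dict[str, list[SegmentMapping]]:
    """Parse PSL from translated alignments of coding segments.

    Query names follow ``<protein_id>_seg<k>``.  Per segment only the
    top-scoring alignment is kept (score = matches - mismatches - gap
    openings); identity = matches/(matches+mismatches) and coverage =
    aligned query bases / query length must pass the thresholds.
    """
    best: dict[tuple[str, int], tuple[float, SegmentMapping]] = {}
    for lineno, line in enumerate(_lines(path), start=1):
        s = line.strip()
        if not s or s.startswith(("psLayout", "match", "#")) or set(s) <= {"-"}:
            continue
        cols = s.split()
        if len(cols) < _PSL_MIN_COLS:
            raise ParseError(
                f"{path}:{lineno}: expected {_PSL_MIN_COLS} PSL columns, "
                f"got {len(cols)}"
            )
        try:
            matches, mismatches = int(cols[0]), int(cols[1])
            q_num_insert, t_num_insert = int(cols[4]), int(cols[6])
            strand = cols[8]
            q_name = cols[9]
            q_size, q_start, q_end = int(cols[10]), int(cols[11]), int(cols[12])
            t_name = cols[13]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if min(matches, mismatches, q_size, q_start, q_end) < 0:
            raise ParseError(f"{path}:{lineno}: negative count in PSL line")
        m = re.match(r"^(.*)_seg(\d+)$", q_name)
        if not m:
            raise ParseError(
                f"{path}:{lineno}: query name {q_name!r} does not follow "
                f"'<protein_id>_seg<k>'"
            )
        pid, seg = m.group(1), int(m.group(2))
        aligned = matches + mismatches
        if aligned == 0 or q_size == 0:
            continue
        identity = matches / aligned
        coverage = (q_end - q_start) / q_size
        score = matches - mismatches - q_num_insert - t_num_insert
        if identity < min_identity or coverage < min_coverage:
            continue
        mapping = SegmentMapping(
            segment_index=seg,
            chromosome=t_name,
            strand=strand[0] if strand else "+",
            identity=identity,
            query_coverage=coverage,
            alignment_score=float(score),
        )
        key = (pid, seg)
        if key not in best or score > best[key][0]:
            best[key] = (score, mapping)
    out: dict[str, list[SegmentMapping]] = {}
    for (pid, _), (_, mapping) in sorted(best.items()):
        out.setdefault(pid, []).append(mapping)
    return out


# ---------------------------------------------------------------------------
# Assembly


def assemble_records(
    fasta_entries: list[tuple[str, str]],
    domain_hits: Optional[dict[str, list[DomainHit]]] = None,
    predictor_calls: Optional[list[RawPredictorCall]] = None,
    mappings: Optional[dict[str, list[SegmentMapping]]] = None,
    *,
    species: str = "",
    descriptions: Optional[dict[str, str]] = None,
    alt_ids: Optional[dict[str, list[tuple[str, str]]]] = None,
    analysis_date: str = "",
    config: EngineConfig = DEFAULT_CONFIG,
) -> list[ProteinRecord]:
    """Merge all annotation sources into one record per FASTA entry.

    Annotation keyed to an id absent from the FASTA is logged and
    dropped; a record with no annotation for some source simply gets
    empty feature lists (the engine will skip evidence-less rules).
    """
    domain_hits = domain_hits or {}
    predictor_calls = predictor_calls or []
    mappings = mappings or {}
    descriptions = descriptions or {}
    alt_ids = alt_ids or {}

    known = {pid for pid, _ in fasta_entries}
    votes_by_pid: dict[str, dict[str, list]] = {}
    for call in predictor_calls:
        if call.protein_id not in known:
            logger.warning(
                "predictor call for unknown protein %r skipped", call.protein_id
            )
            continue
        votes_by_pid.setdefault(call.protein_id, {}).setdefault(
            call.feature_kind, []
        ).append((call.predictor_name, call.called, call.span))
    for pid in set(domain_hits) - known:
        logger.warning("domain hits for unknown protein %r skipped", pid)
    for pid in set(mappings) - known:
        logger.warning("genome mappings for unknown protein %r skipped", pid)

    records = []
    for pid, seq in fasta_entries:
        votes = votes_by_pid.get(pid, {})
        topology = consensus_topology(votes, config)
        records.append(
            ProteinRecord(
                protein_id=pid,
                sequence=seq,
                alt_ids=list(alt_ids.get(pid, [])),
                species=species,
                description=descriptions.get(pid, ""),
                domain_hits=list(domain_hits.get(pid, [])),
                topology=topology,
                segment_mappings=list(mappings.get(pid, [])),
                analysis_date=analysis_date,
            )
        )
    return records


# ---------------------------------------------------------------------------
# helpers


def _lines(path) -> list[str]:
    return Path(path).read_text().splitlines()


def _require_header(lines: list[str], hint: str, path, expected: str) -> None:
    for line in lines:
        if not line.strip():
            continue
        if line.startswith("#") and hint.lstrip("# ").split("-")[0] in line:
            return
        if not line.startswith("#"):
            break
    raise ParseError(f"{path}: unrecognized dialect; expected {expected}")
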