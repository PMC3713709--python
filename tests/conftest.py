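import pytest

from mispredqc import (
    DomainHit,
    EngineConfig,
    ProteinRecord,
    SignalPeptide,
    TopologyFeatures,
    demo_registry_dir,
    load_registries,
)

SEQ400 = "M" + "ACDEFGHIKLMNPQRSTVWY" * 20  # 401 residues, Met start


@pytest.fixture(scope="session")
def registries():
    return load_registries(demo_registry_dir())


@pytest.fixture
def config():
    return EngineConfig()


def make_topology(
    sp_end=None, anchor=None, helices=(), gpi=None, with_votes=True
) -> TopologyFeatures:
    """Build a consensus topology with matching predictor votes."""
    votes = {}
    if with_votes:
        votes["signal_peptide"] = [
            ("SignalP", sp_end is not None),
            ("PrediSi", sp_end is not None),
        ]
        votes["tm_helix"] = (
            [("TMHMM", True)] * len(helices) or [("TMHMM", False)]
        ) + ([("Phobius", True)] * len(helices) or [("Phobius", False)])
        votes["gpi_anchor"] = [("DGPI", gpi is not None)]
        if anchor is not None:
            votes["signal_anchor"] = [("Phobius", True)]
    return TopologyFeatures(
        signal_peptide=SignalPeptide(1, sp_end, sp_end) if sp_end else None,
        signal_anchor=anchor,
        tm_helices=sorted(helices),
        gpi_anchor=gpi,
        predictor_votes=votes,
    )


def make_record(
    pid="P1",
    seq=SEQ400,
    hits=(),
    sp_end=None,
    anchor=None,
    helices=(),
    gpi=None,
    mappings=(),
) -> ProteinRecord:
    return ProteinRecord(
        protein_id=pid,
        sequence=seq,
        domain_hits=list(hits),
        topology=make_topology(sp_end, anchor, helices, gpi),
        segment_mappings=list(mappings),
    )


def hit(acc, name, start, length, copy_index=1, e=1e-20, score=90.0) -> DomainHit:
    return DomainHit(
        family_acc=acc,
        family_name=name,
        copy_index=copy_index,
        ali_start=start,
        ali_end=start + length - 1,
        hmm_start=1,
        hmm_end=length,
        score=score,
        e_value=e,
    )


@pytest.fixture
def secreted_two_domain_record():
    """A secreted protein: signal peptide, one full-length extracellular
    domain and a second extracellular domain present only as a fragment
    far below its family's reference length."""
    return make_record(
        pid="NP_TEST1",
        hits=[
            hit("PF00051.10", "Kringle", 25, 82, e=2.1e-24, score=84.6),
            hit("PF01822.14", "WSC", 150, 40),
        ],
        sp_end=22,
    )
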