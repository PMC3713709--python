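"""Reference resources the consistency rules depend on.

Three small tab-separated files drive the compartment, size and
architecture rules:

``localization.tsv``
    columns ``accession`` and ``compartment`` (one of ``extracellular``,
    ``cytoplasmic``, ``nuclear``); lists Pfam families found exclusively
    in one subcellular compartment.

``domain_sizes.tsv``
    columns ``accession``, ``reference_length`` and optionally
    ``length_sd`` and ``source_n``; families whose instances fall in a
    narrow enough length range to make truncation detectable.

``architectures.tsv``
    one known domain architecture per line, comma-separated accessions in
    N->C order; lines starting ``#`` and blank lines are ignored.

The package bundles illustrative demo registries (a handful of families
per compartment) so that the pipeline runs out of the box; real analyses
should supply registries derived from Pfam/SwissProt annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .model import PFAM_ACC_RE, strip_version

__all__ = [
    "RegistryError",
    "LocalizationRegistry",
    "SizeEntry",
    "SizeRegistry",
    "ArchitectureRegistry",
    "Registries",
    "load_localization_registry",
    "load_size_registry",
    "load_architecture_registry",
    "load_registries",
    "demo_registry_dir",
]

COMPARTMENTS = ("extracellular", "cytoplasmic", "nuclear")

LOCALIZATION_FILE = "localization.tsv"
SIZE_FILE = "domain_sizes.tsv"
ARCHITECTURE_FILE = "architectures.tsv"


class RegistryError(ValueError):
    """A registry file is malformed or violates a registry invariant."""


def _check_accession(acc: str, where: str) -> str:
    acc = acc.strip()
    if not PFAM_ACC_RE.match(acc):
        raise RegistryError(f"{where}: malformed accession {acc!r}")
    return strip_version(acc)


@dataclass(frozen=True)
class LocalizationRegistry:
    """Obligatory-compartment family lists; the three sets are disjoint."""

    extracellular: frozenset[str]
    cytoplasmic: frozenset[str]
    nuclear: frozenset[str]

    def compartment_of(self, accession: str) -> Optional[str]:
        acc = strip_version(accession)
        for name in COMPARTMENTS:
            if acc in getattr(self, name):
                return name
        return None


@dataclass(frozen=True)
class SizeEntry:
    reference_length: int
    length_sd: Optional[float] = None
    source_n: Optional[int] = None


@dataclass(frozen=True)
class SizeRegistry:
    entries: dict[str, SizeEntry] = field(default_factory=dict)

    def get(self, accession: str) -> Optional[SizeEntry]:
        return self.entries.get(strip_version(accession))

    def __contains__(self, accession: str) -> bool:
        return strip_version(accession) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ArchitectureRegistry:
    """Known domain architectures as ordered, version-stripped tuples."""

    architectures: frozenset[tuple[str, ...]] = frozenset()

    def __contains__(self, key: tuple[str, ...]) -> bool:
        return tuple(strip_version(a) for a in key) in self.architectures

    def __len__(self) -> int:
        return len(self.architectures)


@dataclass(frozen=True)
class Registries:
    localization: LocalizationRegistry
    sizes: SizeRegistry
    architectures: ArchitectureRegistry


def load_localization_registry(path) -> LocalizationRegistry:
    df = _read_tsv(path, required=["accession", "compartment"])
    if df.empty:
        raise RegistryError(f"{path}: registry empty")
    sets: dict[str, set[str]] = {name: set() for name in COMPARTMENTS}
    assigned: dict[str, str] = {}
    for row in df.itertuples(index=False):
        acc = _check_accession(str(row.accession), str(path))
        comp = str(row.compartment).strip()
        if comp not in COMPARTMENTS:
            raise RegistryError(
                f"{path}: unknown compartment {comp!r} for {acc} "
                f"(expected one of {', '.join(COMPARTMENTS)})"
            )
        if assigned.get(acc, comp) != comp:
            raise RegistryError(
                f"{path}: {acc} assigned to both {assigned[acc]} and {comp}; "
                f"obligatory compartments must be disjoint"
            )
        assigned[acc] = comp
        sets[comp].add(acc)
    return LocalizationRegistry(
        extracellular=frozenset(sets["extracellular"]),
        cytoplasmic=frozenset(sets["cytoplasmic"]),
        nuclear=frozenset(sets["nuclear"]),
    )


def load_size_registry(path) -> SizeRegistry:
    df = _read_tsv(path, required=["accession", "reference_length"])
    if df.empty:
        raise RegistryError(f"{path}: registry empty")
    entries: dict[str, SizeEntry] = {}
    for row in df.itertuples(index=False):
        acc = _check_accession(str(row.accession), str(path))
        ref = int(row.reference_length)
        if ref <= 0:
            raise RegistryError(
                f"{path}: {acc}: reference_length must be positive, got {ref}"
            )
        sd = getattr(row, "length_sd", None)
        sd = None if sd is None or pd.isna(sd) else float(sd)
        if sd is not None and sd < 0:
            raise RegistryError(f"{path}: {acc}: negative length_sd")
        n = getattr(row, "source_n", None)
        n = None if n is None or pd.isna(n) else int(n)
        entry = SizeEntry(reference_length=ref, length_sd=sd, source_n=n)
        if entries.get(acc, entry) != entry:
            raise RegistryError(f"{path}: duplicate rows for {acc} with different values")
        entries[acc] = entry
    return SizeRegistry(entries=entries)


def load_architecture_registry(path, repeat_collapse: bool = True) -> ArchitectureRegistry:
    """Load known architectures; consecutive repeats of a family are
    collapsed by default so tandem-repeat count differences do not create
    spurious novel architectures."""
    archs: set[tuple[str, ...]] = set()
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        accs = [_check_accession(a, f"{path}:{lineno}") for a in line.split(",")]
        if repeat_collapse:
            accs = collapse_repeats(accs)
        archs.add(tuple(accs))
    if not archs:
        raise RegistryError(f"{path}: registry empty")
    return ArchitectureRegistry(architectures=frozenset(archs))


def collapse_repeats(accs: list[str]) -> list[str]:
    """Collapse consecutive repeats: A,A,B -> A,B (order preserved)."""
    out: list[str] = []
    for a in accs:
        if not out or out[-1] != a:
            out.append(a)
    return out


def load_registries(directory) -> Registries:
    """Load the three registry files from one directory."""
    d = Path(directory)
    return Registries(
        localization=load_localization_registry(d / LOCALIZATION_FILE),
        sizes=load_size_registry(d / SIZE_FILE),
        architectures=load_architecture_registry(d / ARCHITECTURE_FILE),
    )


def demo_registry_dir() -> Path:
    """Directory holding the bundled illustrative demo registries."""
    return Path(resources.files("mispredqc") / "data" / "demo_registries")


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise RegistryError(f"{path}: registry empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RegistryError(
            f"{path}: missing required column(s) {missing}; header must be "
            f"tab-separated with columns {required}"
        )
    return df
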