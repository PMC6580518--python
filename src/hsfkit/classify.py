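"""Class A/B/C assignment from measured HR-A/B architecture.

Plant Hsfs fall into three classes by the structure of the HR-A/B
oligomerization region: class A carries an insertion of about 21 residues
between the HR-A and HR-B blocks, class C about 7, and class B none. The
DBD-to-HR-A/B linker length is class-correlated (A: 9-39, B: 50-78,
C: 14-49 residues) and serves as a secondary consistency check that can
flag, but never override, the insertion-based call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .domains import HsfArchitecture

#: inclusive linker-length ranges per class (secondary check)
LINKER_RANGES: dict[str, tuple[int, int]] = {
    "A": (9, 39),
    "B": (50, 78),
    "C": (14, 49),
}

#: insertion-length decision boundaries bracketing the nominal 21/7/0 sizes
INSERTION_MIN_A = 15
INSERTION_MIN_C = 4

FLAG_LINKER = "LINKER_OUT_OF_RANGE"
FLAG_INCOMPLETE = "ARCHITECTURE_INCOMPLETE"


@dataclass
class HsfClassification:
    """Per-gene class call with diagnostic flags."""

    gene_id: str
    hsf_class: str | None
    subclass: str | None = None
    insertion_len: int | None = None
    linker_len: int | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.hsf_class is not None and FLAG_INCOMPLETE in self.flags:
            raise ValueError("a classified gene cannot be architecture-incomplete")


def class_from_insertion(insertion_len: int) -> str:
    """Primary rule: insertion >= 15 -> A, 4-14 -> C, <= 3 -> B."""
    if insertion_len >= INSERTION_MIN_A:
        return "A"
    if insertion_len >= INSERTION_MIN_C:
        return "C"
    return "B"


def assign_class(arch: HsfArchitecture, gene_id: str = "") -> HsfClassification:
    """Classify a complete architecture.

    The insertion length decides the class; a linker length outside the
    class's range adds LINKER_OUT_OF_RANGE but never changes the call.
    """
    cls = class_from_insertion(arch.insertion_len)
    lo, hi = LINKER_RANGES[cls]
    flags = set()
    if not lo <= arch.linker_len <= hi:
        flags.add(FLAG_LINKER)
    return HsfClassification(
        gene_id=gene_id,
        hsf_class=cls,
        insertion_len=arch.insertion_len,
        linker_len=arch.linker_len,
        flags=frozenset(flags),
    )


def incomplete(gene_id: str) -> HsfClassification:
    """Classification record for a gene whose architecture is incomplete."""
    return HsfClassification(gene_id=gene_id, hsf_class=None,
                             flags=frozenset({FLAG_INCOMPLETE}))


@dataclass
class FamilyClassification:
    """Family-level tally of class calls."""

    counts: dict[str, int]
    per_gene: list[HsfClassification]
    unclassified: list[str] = field(default_factory=list)


def classify_family(
    classifications: Sequence[HsfClassification],
) -> FamilyClassification:
    """Tally class calls; unclassified genes are listed separately."""
    ids = [c.gene_id for c in classifications]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids: {dupes}")
    counts = {"A": 0, "B": 0, "C": 0}
    unclassified = []
    for c in classifications:
        if c.hsf_class is None:
            unclassified.append(c.gene_id)
        else:
            counts[c.hsf_class] += 1
    return FamilyClassification(counts=counts, per_gene=list(classifications),
                                unclassified=sorted(unclassified))


def classifications_from_types(types: Mapping[str, str]) -> list[HsfClassification]:
    """Build classification records from printed type labels (e.g. 'A4a'),
    as when ingesting a published family table."""
    return [
        HsfClassification(gene_id=gid, hsf_class=label[0], subclass=label)
        for gid, label in sorted(types.items())
    ]
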