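"""Core sequence and gene-model types, scaffold-label parsing, pI/Mw
calculators, and family-table summarization.

Coordinates are 1-based inclusive throughout the package, matching the
convention of published Hsf family tables. Molecular weights use average
(not monoisotopic) residue masses and pI uses the Bjellqvist pKa set, the
conventions behind the ExPASy compute pI/Mw tool.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET = frozenset(AA20 + "X")

_DATA = resources.files("hsfkit") / "data"


def _load_json(name: str) -> dict:
    with (_DATA / name).open() as fh:
        return json.load(fh)


_PHYSCHEM = _load_json("physchem.json")
RESIDUE_MASS_DA: dict[str, float] = _PHYSCHEM["residue_mass_da"]
WATER_DA: float = _PHYSCHEM["water_da"]
DEFAULT_PKA: dict = _PHYSCHEM["pka"]


class SequenceError(ValueError):
    """Raised for empty or non-canonical protein sequences."""


class LabelParseError(ValueError):
    """Raised when a scaffold-style chromosome label cannot be parsed."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence keyed by identifier.

    The sequence must be non-empty, uppercase, and restricted to the 20
    canonical residues plus ``X`` (unknown).
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"{self.id}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise SequenceError(f"{self.id}: sequence must be uppercase")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise SequenceError(f"{self.id}: non-canonical residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ChromosomeAssignment:
    """Placement of a gene: homoeologous group 1-7, subgenome A/B/D, arm S/L.

    ``group is None`` and ``subgenome is None`` together denote an unplaced
    gene (scaffold token ``U``).
    """

    group: int | None
    subgenome: str | None
    arm: str | None = None

    def __post_init__(self) -> None:
        if (self.group is None) != (self.subgenome is None):
            raise ValueError("group and subgenome must be both set or both unplaced")

    @property
    def placed(self) -> bool:
        return self.group is not None

    @property
    def token(self) -> str:
        """Chromosome token such as ``4AL``, ``3B`` or ``U``."""
        if not self.placed:
            return "U"
        return f"{self.group}{self.subgenome}{self.arm or ''}"


UNPLACED = ChromosomeAssignment(None, None, None)


@dataclass
class GeneModel:
    """Genomic context of a gene: placement, coordinates and annotation counts."""

    id: str
    chromosome: ChromosomeAssignment
    scaffold_label: str = ""
    start: int = 1
    end: int = 1
    exons: int | None = None
    introns: int | None = None
    est_count: int = 0
    length_bp: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.id}: start {self.start} > end {self.end}")
        if self.est_count < 0:
            raise ValueError(f"{self.id}: negative EST count")
        if (
            self.exons is not None
            and self.introns is not None
            and self.introns != self.exons - 1
        ):
            raise ValueError(f"{self.id}: introns must equal exons - 1")


@dataclass(frozen=True)
class PhysChem:
    """Computed molecular weight (kDa) and isoelectric point (pH units)."""

    mw_kda: float
    pi: float

    def __post_init__(self) -> None:
        if self.mw_kda <= 0:
            raise ValueError("mw_kda must be positive")
        if not 0 < self.pi < 14:
            raise ValueError("pi must lie in (0, 14)")


_CHROM_TOKEN_RE = re.compile(r"^(?:U|(?P<group>[1-7])(?P<sub>[ABD])(?P<arm>[SL])?)$")
_SCAFFOLD_RE = re.compile(r"^scaffold_\d+_(?P<token>[A-Z0-9]+)$")


def parse_chrom_token(token: str) -> ChromosomeAssignment:
    """Parse a bare chromosome token (``4AL``, ``3B``, ``U``)."""
    m = _CHROM_TOKEN_RE.match(token)
    if m is None:
        raise LabelParseError(f"unrecognized chromosome token {token!r}")
    if m.group("group") is None:
        return UNPLACED
    return ChromosomeAssignment(int(m.group("group")), m.group("sub"), m.group("arm"))


def parse_chromosome_label(label: str) -> ChromosomeAssignment:
    """Parse a scaffold-style label such as ``scaffold_288809_4AL``.

    The trailing token is either ``U`` (unplaced) or group digit 1-7,
    subgenome letter A/B/D, and an optional arm letter S/L (survey-sequence
    tables mix arm-qualified tokens like ``4AL`` with bare ones like ``3B``).
    """
    m = _SCAFFOLD_RE.match(label)
    if m is None:
        raise LabelParseError(f"malformed scaffold label {label!r}")
    try:
        return parse_chrom_token(m.group("token"))
    except LabelParseError:
        raise LabelParseError(f"malformed chromosome token in label {label!r}") from None


# ---------------------------------------------------------------------------
# FASTA and table I/O


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable, path: str | Path) -> None:
    """Write records with ``.id`` and ``.sequence`` attributes as FASTA."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_nucleotide_fasta(path: str | Path) -> dict[str, str]:
    """Read a nucleotide FASTA as an id -> sequence mapping (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a gene-model TSV (columns id, scaffold_label, start, end, exons,
    introns and optionally est_count)."""
    df = pd.read_csv(path, sep="\t")
    models = []
    for row in df.itertuples(index=False):
        models.append(
            GeneModel(
                id=str(row.id),
                chromosome=parse_chromosome_label(str(row.scaffold_label)),
                scaffold_label=str(row.scaffold_label),
                start=int(row.start),
                end=int(row.end),
                exons=int(row.exons),
                introns=int(row.introns),
                est_count=int(getattr(row, "est_count", 0)),
            )
        )
    return models


def load_table1() -> pd.DataFrame:
    """Packaged transcription of the 78-gene wheat Hsf inventory table."""
    return pd.read_csv(_DATA / "table1.tsv", sep="\t")


def load_table2() -> pd.DataFrame:
    """Packaged transcription of the wheat Hsf domain-architecture table."""
    return pd.read_csv(_DATA / "table2.tsv", sep="\t")


def table1_gene_models(df: pd.DataFrame | None = None) -> list[GeneModel]:
    df = load_table1() if df is None else df
    models = []
    for row in df.itertuples(index=False):
        models.append(
            GeneModel(
                id=row.name,
                chromosome=parse_chromosome_label(row.scaffold_label),
                scaffold_label=row.scaffold_label,
                start=int(row.start),
                end=int(row.end),
                exons=int(row.exons),
                introns=int(row.introns),
                est_count=int(row.est_count),
                length_bp=int(row.length_bp),
            )
        )
    return models


# ---------------------------------------------------------------------------
# Physicochemical calculators


def compute_mw(p: ProteinRecord) -> float:
    """Molecular weight in kDa: sum of average residue masses plus one water.

    Raises for sequences containing ``X`` (mass undefined).
    """
    try:
        total = sum(RESIDUE_MASS_DA[aa] for aa in p.sequence)
    except KeyError as exc:
        raise SequenceError(f"{p.id}: no mass for residue {exc.args[0]!r}") from None
    return (total + WATER_DA) / 1000.0


def net_charge(sequence: str, ph, pka: Mapping | None = None):
    """Henderson-Hasselbalch net charge of a peptide at pH (vectorized).

    Charged groups: the two termini plus D, E, C, Y (acidic) and H, K, R
    (basic) side chains.
    """
    pka = DEFAULT_PKA if pka is None else pka
    ph = np.asarray(ph, dtype=float)
    counts_acid = {aa: sequence.count(aa) for aa in pka["acidic"]}
    counts_base = {aa: sequence.count(aa) for aa in pka["basic"]}

    def frac_pos(pk):
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def frac_neg(pk):
        return -1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = frac_pos(pka["n_term"]) + frac_neg(pka["c_term"])
    for aa, n in counts_base.items():
        if n:
            charge = charge + n * frac_pos(pka["basic"][aa])
    for aa, n in counts_acid.items():
        if n:
            charge = charge + n * frac_neg(pka["acidic"][aa])
    return charge


def compute_pi(p: ProteinRecord, pka: Mapping | None = None, tol: float = 0.001) -> float:
    """Isoelectric point by bisection on the net-charge curve.

    Net charge is strictly decreasing in pH, so the zero crossing is unique;
    bisection on (0, 14) converges to ``tol`` pH units.
    """
    seq = p.sequence.replace("X", "")
    if not seq:
        raise SequenceError(f"{p.id}: no canonical residues")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def compute_physchem(p: ProteinRecord) -> PhysChem:
    return PhysChem(mw_kda=compute_mw(p), pi=compute_pi(p))


# ---------------------------------------------------------------------------
# Family summarization


@dataclass
class FamilyStats:
    """Family-level summary: class tally, chromosomal distribution and
    physicochemical ranges."""

    n_total: int
    n_per_class: dict[str, int]
    n_placed: int
    n_per_group: dict[int, int]
    n_per_subgenome: dict[str, int]
    n_per_chromosome: dict[str, int]
    max_est: tuple[int, str] | None = None
    aa_length_range: tuple[int, int] | None = None
    mw_range: tuple[float, float] | None = None
    pi_range: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_per_class": self.n_per_class,
            "n_placed": self.n_placed,
            "n_per_group": {str(k): v for k, v in self.n_per_group.items()},
            "n_per_subgenome": self.n_per_subgenome,
            "n_per_chromosome": self.n_per_chromosome,
            "max_est": list(self.max_est) if self.max_est else None,
            "aa_length_range": list(self.aa_length_range) if self.aa_length_range else None,
            "mw_range": list(self.mw_range) if self.mw_range else None,
            "pi_range": list(self.pi_range) if self.pi_range else None,
        }


def summarize_family(
    genes: Sequence[GeneModel],
    classes: Mapping[str, str] | None = None,
    physchem: Mapping[str, PhysChem] | None = None,
    aa_lengths: Mapping[str, int] | None = None,
) -> FamilyStats:
    """Summarize a family: distribution counts, class tally and ranges.

    Unplaced genes are excluded from per-group / per-subgenome /
    per-chromosome counts but included in ``n_total``.
    """
    ids = [g.id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids: {dupes}")

    per_group: dict[int, int] = {}
    per_sub: dict[str, int] = {}
    per_chrom: dict[str, int] = {}
    n_placed = 0
    for g in genes:
        chrom = g.chromosome
        if not chrom.placed:
            continue
        n_placed += 1
        per_group[chrom.group] = per_group.get(chrom.group, 0) + 1
        per_sub[chrom.subgenome] = per_sub.get(chrom.subgenome, 0) + 1
        per_chrom[chrom.token] = per_chrom.get(chrom.token, 0) + 1

    per_class: dict[str, int] = {}
    if classes:
        for gid in ids:
            if gid in classes:
                c = classes[gid]
                per_class[c] = per_class.get(c, 0) + 1

    max_est = None
    ests = [(g.est_count, g.id) for g in genes]
    if ests:
        best = max(ests, key=lambda t: (t[0], t[1]))
        max_est = (best[0], best[1])

    aa_range = None
    if aa_lengths:
        vals = [aa_lengths[g] for g in ids if g in aa_lengths]
        if vals:
            aa_range = (min(vals), max(vals))

    mw_range = pi_range = None
    if physchem:
        mws = [physchem[g].mw_kda for g in ids if g in physchem]
        pis = [physchem[g].pi for g in ids if g in physchem]
        if mws:
            mw_range = (min(mws), max(mws))
            pi_range = (min(pis), max(pis))

    return FamilyStats(
        n_total=len(genes),
        n_per_class=dict(sorted(per_class.items())),
        n_placed=n_placed,
        n_per_group=dict(sorted(per_group.items())),
        n_per_subgenome=dict(sorted(per_sub.items())),
        n_per_chromosome=dict(sorted(per_chrom.items())),
        max_est=max_est,
        aa_length_range=aa_range,
        mw_range=mw_range,
        pi_range=pi_range,
    )


def summarize_table1() -> FamilyStats:
    """FamilyStats recomputed from the packaged family-table transcription."""
    df1 = load_table1()
    df2 = load_table2()
    genes = table1_gene_models(df1)
    classes = {row.name: row.type[0] for row in df2.itertuples(index=False)}
    physchem = {
        row.name: PhysChem(mw_kda=float(row.mw_kda), pi=float(row.pi))
        for row in df1.itertuples(index=False)
    }
    aa_lengths = {row.name: int(row.aa_length) for row in df1.itertuples(index=False)}
    return summarize_family(genes, classes, physchem, aa_lengths)
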