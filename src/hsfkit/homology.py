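"""Candidate identification by local protein alignment.

Optimal Smith-Waterman local alignment with affine gaps (via
Bio.Align.PairwiseAligner) plus Karlin-Altschul E-values, the family
screening filter chain (E-value and identity thresholds, locus-level
deduplication), and EST support counting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .seqcore import GeneModel, ProteinRecord, SequenceError


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring: substitution matrix, affine gap penalties and the
    Karlin-Altschul parameters used for E-values.

    Defaults are the standard gapped protein-search constants
    (BLOSUM62, gap open 11 / extend 1, lambda 0.267, K 0.041). A gap of
    length k costs ``gap_open + k * gap_extend``.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    k: float = 0.041
    match: float | None = None  # simple match/mismatch scoring overrides matrix
    mismatch: float | None = None

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")


@dataclass(frozen=True)
class AlignmentResult:
    """Statistics of one optimal local alignment."""

    query_id: str
    subject_id: str
    score: float
    alignment_length: int
    identities: int
    identity_pct: float
    coverage_longer_pct: float
    evalue: float

    def __post_init__(self) -> None:
        if not (0 <= self.identity_pct <= 100 and 0 <= self.coverage_longer_pct <= 100):
            raise ValueError("percentages must lie in [0, 100]")
        if self.identities > self.alignment_length:
            raise ValueError("identities cannot exceed alignment length")


@lru_cache(maxsize=8)
def _protein_aligner(matrix: str, gap_open: float, gap_extend: float,
                     match: float | None, mismatch: float | None,
                     mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if match is not None:
        aligner.match_score = match
        aligner.mismatch_score = mismatch if mismatch is not None else -match
    else:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    # first gap residue costs open+extend, each further residue costs extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def evalue(score: float, m: int, n: int, s: ScoringScheme) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * score)."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence/database lengths must be positive")
    return s.k * m * n * math.exp(-s.lam * score)


def local_align(
    a: ProteinRecord,
    b: ProteinRecord,
    s: ScoringScheme | None = None,
    db_length: int | None = None,
) -> AlignmentResult:
    """Optimal local alignment of two proteins under scheme ``s``.

    ``identity_pct`` is identities over aligned columns (gaps included);
    ``coverage_longer_pct`` is the aligned span on the longer sequence over
    its length. ``db_length`` (default: len(b)) sets the search-space size n
    for the E-value.
    """
    s = s or ScoringScheme()
    if not a.sequence or not b.sequence:
        raise SequenceError("cannot align empty sequences")
    aligner = _protein_aligner(s.matrix, s.gap_open, s.gap_extend, s.match, s.mismatch)
    alignments = aligner.align(a.sequence, b.sequence)
    try:
        best = alignments[0]
    except IndexError:  # no positive-scoring local alignment
        return AlignmentResult(a.id, b.id, 0.0, 0, 0, 0.0, 0.0,
                               evalue(0.0, len(a), db_length or len(b), s))
    counts = best.counts()
    identities = counts.identities
    aln_len = counts.identities + counts.mismatches + counts.gaps
    # span on the longer of the two sequences
    blocks_a, blocks_b = best.aligned
    longer_blocks, longer_len = (
        (blocks_a, len(a)) if len(a) >= len(b) else (blocks_b, len(b))
    )
    if len(longer_blocks):
        span = int(longer_blocks[-1][1]) - int(longer_blocks[0][0])
    else:
        span = 0
    return AlignmentResult(
        query_id=a.id,
        subject_id=b.id,
        score=float(best.score),
        alignment_length=int(aln_len),
        identities=int(identities),
        identity_pct=100.0 * identities / aln_len if aln_len else 0.0,
        coverage_longer_pct=100.0 * span / longer_len,
        evalue=evalue(float(best.score), len(a), db_length or len(b), s),
    )


class PairwiseCache:
    """Lazy cache of pairwise alignment results keyed by unordered id pair.

    Shared between homoeolog grouping and duplication detection so each
    protein pair is aligned once.
    """

    def __init__(self, proteins: Mapping[str, ProteinRecord],
                 scheme: ScoringScheme | None = None):
        self.proteins = dict(proteins)
        self.scheme = scheme or ScoringScheme()
        self._cache: dict[frozenset, AlignmentResult] = {}

    def get(self, id_a: str, id_b: str) -> AlignmentResult:
        key = frozenset((id_a, id_b))
        if key not in self._cache:
            first, second = sorted((id_a, id_b))
            self._cache[key] = local_align(
                self.proteins[first], self.proteins[second], self.scheme
            )
        return self._cache[key]


# ---------------------------------------------------------------------------
# Screening


@dataclass
class ScreenHit:
    """Best-query screening outcome for one proteome entry."""

    id: str
    best_query: str
    evalue: float
    identity_pct: float
    coverage_longer_pct: float
    passed: bool


def screen_candidates(
    proteome: Sequence[ProteinRecord],
    gene_models: Mapping[str, GeneModel],
    queries: Sequence[ProteinRecord],
    s: ScoringScheme | None = None,
    e_max: float = 1e-5,
    id_min: float = 50.0,
) -> tuple[list[str], list[ScreenHit]]:
    """Screen a proteome against known Hsf queries.

    A protein passes if some query alignment has E <= ``e_max`` and aligned
    identity >= ``id_min`` percent. Among passers whose gene models overlap
    on the same scaffold, only the longest protein is retained (redundant
    isoforms at one locus), ties broken by lexicographic id. Returns the
    sorted candidate id list plus per-protein hit reports.
    """
    s = s or ScoringScheme()
    if not queries:
        warnings.warn("empty query set: no candidates can be identified")
        return [], []
    db_length = sum(len(p) for p in proteome)
    hits: list[ScreenHit] = []
    passers: list[str] = []
    for prot in sorted(proteome, key=lambda p: p.id):
        best: AlignmentResult | None = None
        for q in queries:
            res = local_align(prot, q, s, db_length=db_length)
            if best is None or (res.evalue, -res.identity_pct) < (
                best.evalue, -best.identity_pct
            ):
                best = res
        passed = best.evalue <= e_max and best.identity_pct >= id_min
        hits.append(
            ScreenHit(prot.id, best.subject_id, best.evalue, best.identity_pct,
                      best.coverage_longer_pct, passed)
        )
        if passed:
            passers.append(prot.id)

    retained = _dedup_same_locus(passers, proteome, gene_models)
    return sorted(retained), hits


def _dedup_same_locus(
    passers: Sequence[str],
    proteome: Sequence[ProteinRecord],
    gene_models: Mapping[str, GeneModel],
) -> list[str]:
    """Keep one protein (the longest) per set of overlapping gene intervals
    sharing a scaffold."""
    lengths = {p.id: len(p) for p in proteome}
    by_scaffold: dict[str, list[str]] = {}
    no_model: list[str] = []
    for pid in passers:
        gm = gene_models.get(pid)
        if gm is None:
            no_model.append(pid)
            continue
        by_scaffold.setdefault(gm.scaffold_label or gm.chromosome.token, []).append(pid)

    retained = list(no_model)
    for scaffold, ids in by_scaffold.items():
        ids = sorted(ids, key=lambda i: gene_models[i].start)
        # connected components of overlapping [start, end] intervals
        component: list[str] = []
        comp_end = -1
        for pid in ids:
            gm = gene_models[pid]
            if component and gm.start <= comp_end:
                component.append(pid)
                comp_end = max(comp_end, gm.end)
            else:
                if component:
                    retained.append(_longest(component, lengths))
                component = [pid]
                comp_end = gm.end
        if component:
            retained.append(_longest(component, lengths))
    return retained


def _longest(ids: Sequence[str], lengths: Mapping[str, int]) -> str:
    return min(ids, key=lambda i: (-lengths[i], i))


# ---------------------------------------------------------------------------
# EST support


def est_identity(est: str, cds: str) -> float:
    """Percent identity of the best infix alignment of an EST into a CDS
    (edit-distance based; 100 means the EST occurs exactly)."""
    if not est or not cds:
        return 0.0
    res = edlib.align(est, cds, mode="HW", task="distance")
    return 100.0 * (1.0 - res["editDistance"] / len(est))


def est_support(
    cds: str,
    ests: Mapping[str, str] | Sequence[str],
    id_min: float = 95.0,
    len_min: int = 100,
) -> tuple[int, str]:
    """Count ESTs supporting a CDS: best infix alignment with identity >=
    ``id_min`` percent and EST length >= ``len_min`` bp.

    Returns (count, status) where status is "supported" or "unsupported";
    an unsupported gene is flagged, never removed.
    """
    seqs = list(ests.values()) if isinstance(ests, Mapping) else list(ests)
    count = sum(
        1 for est in seqs if len(est) >= len_min and est_identity(est, cds) >= id_min
    )
    return count, ("supported" if count else "unsupported")


def assign_ests(
    cds_by_gene: Mapping[str, str],
    ests: Mapping[str, str],
    id_min: float = 95.0,
    len_min: int = 100,
) -> dict[str, int]:
    """Assign each EST to its single best-matching CDS and tally per gene.

    Best-hit assignment keeps homoeologous copies (which share high CDS
    identity) from double-counting each other's ESTs: the parent gene always
    wins at higher identity.
    """
    counts = {gid: 0 for gid in cds_by_gene}
    gene_ids = sorted(cds_by_gene)
    for est_id in sorted(ests):
        est = ests[est_id]
        if len(est) < len_min:
            continue
        best_gene, best_ident = None, -1.0
        for gid in gene_ids:
            ident = est_identity(est, cds_by_gene[gid])
            if ident > best_ident:
                best_gene, best_ident = gid, ident
        if best_gene is not None and best_ident >= id_min:
            counts[best_gene] += 1
    return counts
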