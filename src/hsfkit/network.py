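"""Orthology-based projection of a reference interactome and hypergeometric
functional enrichment.

Family genes are mapped to a reference proteome (e.g. a model dicot) by
reciprocal best hit; each mapped gene inherits the interaction partners of
its ortholog. Term enrichment of the interacting set uses the exact
upper-tail hypergeometric probability with Benjamini-Hochberg adjustment
(Bonferroni available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .homology import ScoringScheme, local_align
from .seqcore import ProteinRecord


@dataclass
class OrthologMap:
    """Injective query -> reference mapping from reciprocal best hits."""

    mapping: dict[str, str]
    identity: dict[str, float]
    coverage: dict[str, float]

    def __post_init__(self) -> None:
        refs = list(self.mapping.values())
        if len(set(refs)) != len(refs):
            raise ValueError("ortholog map must be injective")


def map_orthologs(
    queries: Sequence[ProteinRecord],
    reference: Sequence[ProteinRecord],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-5,
    id_min: float = 50.0,
) -> OrthologMap:
    """Reciprocal best hits between queries and a reference proteome,
    subject to E-value and aligned-identity thresholds."""
    scheme = scheme or ScoringScheme()
    if not queries or not reference:
        raise ValueError("both sequence sets must be non-empty")
    db_q = sum(len(p) for p in queries)
    db_r = sum(len(p) for p in reference)
    results = {}
    for q in queries:
        for r in reference:
            results[(q.id, r.id)] = local_align(q, r, scheme, db_length=db_r)

    def best_ref(q: ProteinRecord) -> str:
        return min((r.id for r in reference),
                   key=lambda rid: (-results[(q.id, rid)].score, rid))

    def best_query(rid: str) -> str:
        return min((q.id for q in queries),
                   key=lambda qid: (-results[(qid, rid)].score, qid))

    mapping, ident, cov = {}, {}, {}
    for q in sorted(queries, key=lambda p: p.id):
        rid = best_ref(q)
        res = results[(q.id, rid)]
        if best_query(rid) != q.id:
            continue
        if res.evalue > e_max or res.identity_pct < id_min:
            continue
        mapping[q.id] = rid
        ident[q.id] = res.identity_pct
        cov[q.id] = res.coverage_longer_pct
    return OrthologMap(mapping, ident, cov)


@dataclass
class ProjectedNetwork:
    """Interaction edges inherited through orthology."""

    edges: set[tuple[str, str]]  # (family gene, partner)
    degree: dict[str, int]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        """Mean partners per mapped gene (unmapped genes excluded)."""
        if not self.degree:
            return 0.0
        return sum(self.degree.values()) / len(self.degree)


def project_network(
    orthologs: OrthologMap,
    reference_edges: Iterable[tuple[str, str]],
) -> ProjectedNetwork:
    """Each mapped query inherits all undirected edges of its reference
    ortholog; self-loops dropped, edge set deduplicated."""
    adj: dict[str, set[str]] = {}
    for a, b in reference_edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    edges = set()
    degree = {}
    for q in sorted(orthologs.mapping):
        ref = orthologs.mapping[q]
        partners = {p for p in adj.get(ref, set()) if p != ref}
        for p in sorted(partners):
            edges.add((q, p))
        degree[q] = len(partners)
    return ProjectedNetwork(edges=edges, degree=degree)


@dataclass
class EnrichmentResult:
    term: str
    k: int  # annotated genes in the set
    K: int  # annotated genes in the universe
    n: int  # set size
    N: int  # universe size
    p: float
    q: float
    significant: bool

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("k cannot exceed min(K, n)")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    gene_set: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.01,
    method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Term over-representation of ``gene_set`` within ``universe``.

    p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n); q-values by
    Benjamini-Hochberg (or Bonferroni); results with q <= ``alpha`` are
    flagged significant; output sorted by p then term id.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    N, n = len(universe), len(gene_set)
    terms = sorted(annotation)
    raw = []
    for term in terms:
        annotated = set(annotation[term]) & universe
        K = len(annotated)
        k = len(annotated & gene_set)
        raw.append((term, k, K, hypergeom_pvalue(k, K, n, N)))
    if not raw:
        return []
    pvals = [r[3] for r in raw]
    if method == "bonferroni":
        qvals = [min(1.0, p * len(pvals)) for p in pvals]
    else:
        qvals = list(multipletests(pvals, method=method)[1])
    out = [
        EnrichmentResult(term, k, K, n, N, p, q, q <= alpha)
        for (term, k, K, p), q in zip(raw, qvals)
    ]
    return sorted(out, key=lambda r: (r.p, r.term))
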