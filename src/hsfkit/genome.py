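"""Chromosomal distribution, homoeolog grouping across A/B/D subgenomes,
duplication detection under the strict >80% identity / >80% coverage rule,
and link-table export.

Homoeologs are detected per homoeologous chromosome group (1-7) as mutual
best hits between subgenomes that also satisfy the 80/80 rule; triangulated
triads take precedence over pairs. Duplicate gene pairs are all unordered
pairs passing the strict 80/80 rule outside any one homoeolog group; because
a duplication that predates homoeolog divergence necessarily links every
member of the two groups, a collapse step reduces such clusters to one
representative pair per group pair for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .homology import AlignmentResult, PairwiseCache
from .seqcore import GeneModel, ProteinRecord

SUBGENOMES = ("A", "B", "D")


@dataclass
class HomoeologGroup:
    """A homoeolog group: gene copies of one locus across subgenomes."""

    group_id: str
    chrom_group: int | None
    members: dict[str, str]  # subgenome -> gene id

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 3:
            raise ValueError("a group holds 1-3 members")

    @property
    def kind(self) -> str:
        return {3: "triad", 2: "pair", 1: "singleton"}[len(self.members)]

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.members.values())


@dataclass(frozen=True)
class DupPair:
    """A duplicated gene pair passing the strict 80/80 rule."""

    gene_a: str
    gene_b: str
    identity_pct: float
    coverage_longer_pct: float
    mode: str  # same_chromosome | segmental

    def __post_init__(self) -> None:
        if not (self.identity_pct > 80.0 and self.coverage_longer_pct > 80.0):
            raise ValueError("duplicate pairs require identity and coverage > 80")

    @property
    def key(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class GroupingSummary:
    n_triads: int
    n_pairs: int
    n_singletons: int

    @property
    def family_size(self) -> int:
        return 3 * self.n_triads + 2 * self.n_pairs + self.n_singletons


def _passes_8080(res: AlignmentResult, id_min: float, cov_min: float) -> bool:
    return res.identity_pct > id_min and res.coverage_longer_pct > cov_min


def group_homoeologs(
    genes: Mapping[str, GeneModel],
    cache: PairwiseCache,
    id_min: float = 80.0,
    cov_min: float = 80.0,
) -> tuple[list[HomoeologGroup], GroupingSummary]:
    """Group genes into homoeolog triads/pairs/singletons.

    Within each chromosome group, candidate homoeolog pairs are mutual best
    hits (by alignment score) across subgenomes meeting the strict 80/80
    rule. Triangulated triads (all three cross-subgenome edges present) are
    preferred over pairs; each gene joins at most one group. Input order
    does not affect the outcome.
    """
    by_cg: dict[int, dict[str, list[str]]] = {}
    for gid in sorted(genes):
        chrom = genes[gid].chromosome
        if chrom.placed:
            by_cg.setdefault(chrom.group, {}).setdefault(chrom.subgenome, []).append(gid)

    groups: list[HomoeologGroup] = []
    assigned: set[str] = set()
    n_group = 0
    for cg in sorted(by_cg):
        subs = by_cg[cg]
        edges: dict[tuple[str, str], AlignmentResult] = {}
        for i, sub_a in enumerate(SUBGENOMES):
            for sub_b in SUBGENOMES[i + 1:]:
                if sub_a not in subs or sub_b not in subs:
                    continue
                for pair in _mutual_best(subs[sub_a], subs[sub_b], cache):
                    res = cache.get(*pair)
                    if _passes_8080(res, id_min, cov_min):
                        edges[pair] = res

        # triads: one gene per subgenome, all three edges mutual-best and 80/80
        triads = []
        for (a, b) in sorted(edges):
            for (c, d) in sorted(edges):
                third = {a, b} ^ {c, d}
                if len(third) != 2 or not ({a, b} & {c, d}):
                    continue
                e3 = tuple(sorted(third))
                if e3 in edges:
                    trio = tuple(sorted({a, b, c, d}))
                    if len(trio) == 3 and trio not in [t[0] for t in triads]:
                        ident = sum(edges[e].identity_pct
                                    for e in _trio_edges(trio))
                        triads.append((trio, ident))
        for trio, _ in sorted(triads, key=lambda t: (-t[1], t[0])):
            if any(g in assigned for g in trio):
                continue
            members = {genes[g].chromosome.subgenome: g for g in trio}
            n_group += 1
            groups.append(HomoeologGroup(f"HG{n_group:03d}", cg, members))
            assigned.update(trio)

        # remaining mutual 80/80 edges become pairs (best identity first)
        for (a, b) in sorted(edges, key=lambda e: (-edges[e].identity_pct, e)):
            if a in assigned or b in assigned:
                continue
            members = {genes[g].chromosome.subgenome: g for g in (a, b)}
            n_group += 1
            groups.append(HomoeologGroup(f"HG{n_group:03d}", cg, members))
            assigned.update((a, b))

    for gid in sorted(genes):
        if gid in assigned:
            continue
        chrom = genes[gid].chromosome
        sub = chrom.subgenome if chrom.placed else "A"
        n_group += 1
        groups.append(
            HomoeologGroup(f"HG{n_group:03d}",
                           chrom.group if chrom.placed else None, {sub: gid})
        )
    kinds = [g.kind for g in groups]
    summary = GroupingSummary(kinds.count("triad"), kinds.count("pair"),
                              kinds.count("singleton"))
    return groups, summary


def _trio_edges(trio: tuple[str, str, str]) -> list[tuple[str, str]]:
    a, b, c = trio
    return [tuple(sorted(p)) for p in ((a, b), (a, c), (b, c))]


def _mutual_best(ids_a: Sequence[str], ids_b: Sequence[str],
                 cache: PairwiseCache) -> list[tuple[str, str]]:
    """Mutual best hits by score between two id sets (ties: smaller id)."""
    def best(src: str, pool: Sequence[str]) -> str:
        return min(pool, key=lambda t: (-cache.get(src, t).score, t))

    out = []
    for a in ids_a:
        b = best(a, ids_b)
        if best(b, ids_a) == a:
            out.append(tuple(sorted((a, b))))
    return sorted(set(out))


# ---------------------------------------------------------------------------
# Duplications


def find_duplicates(
    genes: Mapping[str, GeneModel],
    cache: PairwiseCache,
    groups: Sequence[HomoeologGroup] = (),
    id_min: float = 80.0,
    cov_min: float = 80.0,
) -> list[DupPair]:
    """All unordered gene pairs with identity > ``id_min`` and coverage of
    the longer gene > ``cov_min`` (strict), excluding pairs inside one
    homoeolog group. Mode is same_chromosome iff both genes carry an
    identical chromosome token, else segmental.
    """
    group_of = {}
    for grp in groups:
        for gid in grp.gene_ids:
            group_of[gid] = grp.group_id
    ids = sorted(genes)
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if group_of.get(a) is not None and group_of.get(a) == group_of.get(b):
                continue
            res = cache.get(a, b)
            if not _passes_8080(res, id_min, cov_min):
                continue
            same = (
                genes[a].chromosome.placed
                and genes[a].chromosome.token == genes[b].chromosome.token
            )
            out.append(
                DupPair(a, b, res.identity_pct, res.coverage_longer_pct,
                        "same_chromosome" if same else "segmental")
            )
    return out


def collapse_duplicate_pairs(
    dups: Sequence[DupPair], groups: Sequence[HomoeologGroup]
) -> list[DupPair]:
    """One representative duplicate pair per pair of homoeolog groups.

    A duplication that predates homoeolog divergence links every member of
    the two descendant groups pairwise; the highest-identity pair (ties by
    gene ids) represents the event.
    """
    group_of = {}
    for grp in groups:
        for gid in grp.gene_ids:
            group_of[gid] = grp.group_id
    best: dict[frozenset, DupPair] = {}
    for dup in sorted(dups, key=lambda d: (-d.identity_pct, d.gene_a, d.gene_b)):
        ga = group_of.get(dup.gene_a, dup.gene_a)
        gb = group_of.get(dup.gene_b, dup.gene_b)
        key = frozenset((ga, gb))
        if key not in best:
            best[key] = dup
    return sorted(best.values(), key=lambda d: (d.gene_a, d.gene_b))


# ---------------------------------------------------------------------------
# Reports


def distribution_report(genes: Iterable[GeneModel]) -> dict:
    """Per-chromosome / per-group / per-subgenome counts over placed genes;
    unplaced genes are reported separately."""
    per_group: dict[int, int] = {}
    per_sub: dict[str, int] = {}
    per_chrom: dict[str, int] = {}
    unplaced = 0
    total = 0
    for g in genes:
        total += 1
        if not g.chromosome.placed:
            unplaced += 1
            continue
        per_group[g.chromosome.group] = per_group.get(g.chromosome.group, 0) + 1
        per_sub[g.chromosome.subgenome] = per_sub.get(g.chromosome.subgenome, 0) + 1
        per_chrom[g.chromosome.token] = per_chrom.get(g.chromosome.token, 0) + 1
    return {
        "n_total": total,
        "n_placed": total - unplaced,
        "n_unplaced": unplaced,
        "per_group": dict(sorted(per_group.items())),
        "per_subgenome": dict(sorted(per_sub.items())),
        "per_chromosome": dict(sorted(per_chrom.items())),
    }


def export_links(
    groups: Sequence[HomoeologGroup],
    dups: Sequence[DupPair],
    genes: Mapping[str, GeneModel],
) -> list[str]:
    """Plain-text link records (Circos dialect): one line per relation,
    ``chrA startA endA chrB startB endB relation``. Homoeolog groups emit
    the complete graph over their members; records with an unplaced member
    are skipped with a warning comment."""
    lines = ["# chrA startA endA chrB startB endB relation"]

    def record(a: str, b: str, relation: str) -> str | None:
        ga, gb = genes[a], genes[b]
        if not (ga.chromosome.placed and gb.chromosome.placed):
            return f"# skipped {a}-{b}: unplaced member"
        return (f"{ga.chromosome.token} {ga.start} {ga.end} "
                f"{gb.chromosome.token} {gb.start} {gb.end} {relation}")

    for grp in groups:
        members = grp.gene_ids
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                line = record(a, b, "homoeolog")
                if line:
                    lines.append(line)
    for dup in dups:
        line = record(dup.gene_a, dup.gene_b, dup.mode)
        if line:
            lines.append(line)
    return lines
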