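"""Seeded synthetic hexaploid dataset with a ground-truth manifest.

The generator emits a miniature A/B/D-subgenome proteome containing planted
Hsf genes of classes A, B and C, arranged into homoeolog triads, pairs and
singletons, with duplicate gene pairs (same-chromosome and segmental),
decoy proteins, EST sets, a reference interactome with planted orthologs,
FPKM expression tables and qPCR Ct tables with known fold changes. Every
planted structure is recorded in the truth manifest so downstream stages
can be validated exactly.

Planted proteins instantiate the packaged DBD profile and carry an ideal
heptad HR-A/B whose inter-block insertion is class-specific (A: 21, C: 7,
B: none; insertions preserve the heptad phase, as in real Hsfs). Homoeolog
and duplicate divergence is planted as an exact number of substitutions
(not a Bernoulli rate), so identity thresholds are met with deterministic
margins at any seed; hydrophobic-core positions of the HR blocks mutate
conservatively (among L/I/V/M/F) and planted signal motifs are excluded
from mutation, keeping manifest coordinates exact. Decoys either lack the
DBD entirely (coil only) or carry a diverged remnant DBD (35% consensus
match) that falls below both the homology-screen identity threshold and the
profile-scan threshold, emulating distant non-Hsf winged-helix proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqcore import (
    AA20,
    ChromosomeAssignment,
    GeneModel,
    ProteinRecord,
    _load_json,
    write_fasta,
)

_DBD = _load_json("dbd_profile.json")

#: inclusive linker ranges used when planting (same as the classifier's)
_LINKER_RANGES = {"A": (9, 39), "B": (50, 78), "C": (14, 49)}
_INSERTIONS = {"A": 21, "B": 0, "C": 7}
_HEPTADS_PER_BLOCK = 4  # 28-residue HR blocks

_CORE_AA = "LIVMF"
_POLAR = "EKQASNRDT"
_NOCOIL = "PGSTNQDEKRH"  # flexible/charged, no hydrophobic-core residues

_SUBCLASSES = {
    "A": ["A1a", "A2a", "A2b", "A2e", "A3", "A4a", "A4d", "A5", "A6a", "A6b",
          "A7b", "A8"],
    "B": ["B1", "B2a", "B2c", "B2d", "B4b", "B4c"],
    "C": ["C1a", "C1b", "C2a", "C2b"],
}

_NLS_MOTIFS = {"A": "KKRR", "B": "KRSR", "C": "KRPR"}
_NES_MOTIF = "LTEQMGLL"
_AHA_MOTIF = "DSFWEQFLCA"


class ConfigError(ValueError):
    """Raised for inconsistent generator configurations."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the structure of the wheat Hsf family survey: 78 family
    genes (38 class A, 16 B, 24 C) organized as 17 triads, 7 pairs and 13
    singletons, with 3 same-chromosome and 14 segmental duplicate pairs,
    plus decoys, 15 planted orthologs inheriting 420 interaction edges, and
    13 qPCR genes with planted fold changes.
    """

    class_counts: dict = field(
        default_factory=lambda: {"A": 38, "B": 16, "C": 24})
    n_triads: int = 17
    n_pairs: int = 7
    n_singletons: int = 13
    n_duplicate_pairs_same_chrom: int = 3
    n_duplicate_pairs_segmental: int = 14
    n_decoys_no_dbd: int = 11
    n_decoys_no_coil: int = 11
    homoeolog_divergence: float = 0.05
    duplicate_divergence: float = 0.045
    intra_class_divergence: float = 0.12
    query_divergence: float = 0.2
    est_per_gene: dict | None = None
    est_max: int = 8
    n_unsupported: int = 2
    n_orthologs: int = 15
    ortholog_divergence: float = 0.10
    network_edges_total: int = 420
    n_reference_decoys: int = 5
    tissues: tuple = ("grain", "leaf", "root", "spike", "stem")
    fpkm_replicates: int = 3
    fpkm_dispersion: float = 0.2
    ct_effects: dict | None = None
    ct_noise_sd: float = 0.05
    ct_replicates: int = 3
    reference_gene: str = "actin"
    control_condition: str = "H17CK"
    treated_condition: str = "H17Cd"
    seed: int = 0

    @property
    def family_size(self) -> int:
        return sum(self.class_counts.values())

    def validate(self) -> None:
        counts = [
            self.n_triads, self.n_pairs, self.n_singletons,
            self.n_duplicate_pairs_same_chrom, self.n_duplicate_pairs_segmental,
            self.n_decoys_no_dbd, self.n_decoys_no_coil,
        ]
        if any(c < 0 for c in counts) or any(v < 0 for v in self.class_counts.values()):
            raise ConfigError("all counts must be non-negative")
        expected = 3 * self.n_triads + 2 * self.n_pairs + self.n_singletons
        if expected != self.family_size:
            raise ConfigError(
                f"3*triads + 2*pairs + singletons = {expected} does not match "
                f"total planted family size {self.family_size}")
        for cls, (lo, hi) in _LINKER_RANGES.items():
            if not lo <= hi:
                raise ConfigError(f"invalid linker range for class {cls}")


# ---------------------------------------------------------------------------
# class -> group-kind allocation


def _allocate_classes(cfg: GeneratorConfig) -> list[tuple[str, str]]:
    """Assign a class to each homoeolog group so that member totals match
    class_counts exactly. Returns [(kind, class)] with kinds in the order
    triad*, pair*, singleton*."""
    items = [(c, n) for c, n in sorted(cfg.class_counts.items()) if n > 0]

    def solve(idx: int, T: int, P: int, S: int):
        if idx == len(items):
            return [] if (T, P, S) == (0, 0, 0) else None
        cls, target = items[idx]
        for t in range(min(T, target // 3), -1, -1):
            rem2 = target - 3 * t
            for p in range(min(P, rem2 // 2), -1, -1):
                s = rem2 - 2 * p
                if s <= S:
                    rest = solve(idx + 1, T - t, P - p, S - s)
                    if rest is not None:
                        return [(cls, t, p, s)] + rest
        return None

    sol = solve(0, cfg.n_triads, cfg.n_pairs, cfg.n_singletons)
    if sol is None:
        raise ConfigError("class counts cannot be partitioned into the "
                          "requested triads/pairs/singletons")
    out = []
    for kind, pos in (("triad", 1), ("pair", 2), ("singleton", 3)):
        for (cls, *alloc) in sol:
            out += [(kind, cls)] * alloc[pos - 1]
    return out


def _plan_duplications(cfg: GeneratorConfig, groups: list[dict]) -> list[dict]:
    """Choose duplicate edges: same-chromosome edges between same-class
    singletons, segmental edges between disjoint same-class groups."""
    singles_by_class: dict[str, list[int]] = {}
    all_by_class: dict[str, list[int]] = {}
    for idx, grp in enumerate(groups):
        all_by_class.setdefault(grp["class"], []).append(idx)
        if grp["kind"] == "singleton":
            singles_by_class.setdefault(grp["class"], []).append(idx)

    edges: list[dict] = []
    used: set[int] = set()
    # same-chromosome: consume same-class singleton pairs, largest pool first
    need = cfg.n_duplicate_pairs_same_chrom
    for cls in sorted(singles_by_class, key=lambda c: -len(singles_by_class[c])):
        pool = singles_by_class[cls]
        while need and len([i for i in pool if i not in used]) >= 2:
            free = [i for i in pool if i not in used]
            a, b = free[0], free[1]
            edges.append({"src": a, "dst": b, "mode": "same_chromosome"})
            used.update((a, b))
            need -= 1
    if need:
        raise ConfigError("not enough same-class singletons for the requested "
                          "same-chromosome duplicate pairs")
    # segmental: disjoint same-class pairs among the remaining groups
    need = cfg.n_duplicate_pairs_segmental
    for cls in sorted(all_by_class):
        pool = [i for i in all_by_class[cls] if i not in used]
        while need and len(pool) >= 2:
            a, b = pool.pop(0), pool.pop(0)
            edges.append({"src": a, "dst": b, "mode": "segmental"})
            used.update((a, b))
            need -= 1
    if need:
        raise ConfigError("not enough same-class groups for the requested "
                          "segmental duplicate pairs")
    return edges


# ---------------------------------------------------------------------------
# sequence construction


class _Builder:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.consensus = _DBD["consensus"]

    def background(self, n: int, alphabet: str = AA20) -> str:
        return "".join(self.rng.choice(list(alphabet), size=n))

    def dbd(self, match_prob: float) -> str:
        out = []
        for aa in self.consensus:
            if self.rng.random() < match_prob:
                out.append(aa)
            else:
                others = [x for x in AA20 if x != aa]
                out.append(others[self.rng.integers(len(others))])
        return "".join(out)

    def heptad_block(self, n_heptads: int) -> str:
        out = []
        for _ in range(n_heptads):
            for slot in range(7):
                if slot in (0, 3):
                    pool = "LI" if slot == 0 else "LVM"
                else:
                    pool = _POLAR
                out.append(pool[self.rng.integers(len(pool))])
        return "".join(out)

    def insertion(self, n: int) -> str:
        """Inter-block insertion: heptad-phase preserving, with core slots
        (a/d) held by proline so the coil clearly breaks."""
        out = []
        for i in range(n):
            if i % 7 in (0, 3):
                out.append("P")
            else:
                pool = "GSTNQDE"
                out.append(pool[self.rng.integers(len(pool))])
        return "".join(out)


def _assemble(parts: list[tuple[str, str]], cls: str) -> dict:
    """Assemble (role, seq) parts into a sequence with 1-based feature
    coordinates. Roles: bg, dbd, linker, hra, insertion, hrb, nls, aha, nes."""
    names = {"dbd": "DBD", "hra": "HRA", "insertion": "insertion",
             "hrb": "HRB", "nls": "NLS", "aha": "AHA", "nes": "NES"}
    coords = {}
    pos = 0
    seqs = []
    linker_len = ins_len = 0
    for role, seq in parts:
        if role in names:
            coords[names[role]] = (pos + 1, pos + len(seq))
        if role == "linker":
            linker_len = len(seq)
        if role == "insertion":
            ins_len = len(seq)
        seqs.append(seq)
        pos += len(seq)
    coords["HRAB"] = (coords["HRA"][0], coords["HRB"][1])
    return {
        "sequence": "".join(seqs),
        "coords": coords,
        "parts": parts,
        "class": cls,
        "linker_len": linker_len,
        "insertion_len": ins_len,
    }


def _build_architecture(b: _Builder, cls: str, dbd_match: float = 0.9) -> dict:
    """Construct a fresh planted Hsf protein (a class template)."""
    rng = b.rng
    lo, hi = _LINKER_RANGES[cls]
    parts: list[tuple[str, str]] = [
        ("bg", b.background(int(rng.integers(15, 61)))),
        ("dbd", b.dbd(dbd_match)),
        ("linker", b.background(int(rng.integers(lo, hi + 1)), _NOCOIL)),
        ("hra", b.heptad_block(_HEPTADS_PER_BLOCK)),
    ]
    if _INSERTIONS[cls]:
        parts.append(("insertion", b.insertion(_INSERTIONS[cls])))
    parts += [
        ("hrb", b.heptad_block(_HEPTADS_PER_BLOCK)),
        ("bg", b.background(int(rng.integers(20, 36)), _NOCOIL)),
        ("nls", _NLS_MOTIFS[cls]),
        ("bg", b.background(int(rng.integers(60, 101)))),
    ]
    if cls == "A":
        parts += [
            ("aha", _AHA_MOTIF),
            ("bg", b.background(int(rng.integers(10, 21)))),
            ("nes", _NES_MOTIF),
        ]
    parts.append(("bg", b.background(int(rng.integers(40, 81)))))
    return _assemble(parts, cls)


def _derive_architecture(b: _Builder, template: dict, divergence: float,
                         fresh_linker: bool) -> dict:
    """Derive a new architecture from a template by exact-count substitution
    per part; optionally redraw the linker (new length from the class range).

    Background and DBD parts mutate freely; HR blocks mutate conservatively
    (core slots among hydrophobics, non-core among polars); the insertion
    and signal motifs are copied verbatim so planted coordinates and the
    class criterion stay exact.
    """
    rng = b.rng
    cls = template["class"]
    parts: list[tuple[str, str]] = []
    for role, seq in template["parts"]:
        if role in ("insertion", "nls", "aha", "nes"):
            parts.append((role, seq))
            continue
        if role == "linker" and fresh_linker:
            lo, hi = _LINKER_RANGES[cls]
            parts.append(
                ("linker", b.background(int(rng.integers(lo, hi + 1)), _NOCOIL)))
            continue
        n = int(round(divergence * len(seq)))
        if role in ("hra", "hrb"):
            pools = {i: (_CORE_AA if i % 7 in (0, 3) else _POLAR)
                     for i in range(len(seq))}
        elif role == "linker":
            pools = {i: _NOCOIL for i in range(len(seq))}
        else:
            pools = {}
        mutated = _mutate(seq, n, np.arange(len(seq)), pools, rng)
        parts.append((role, mutated))
    return _assemble(parts, cls)


def _mutation_targets(arch: dict) -> tuple[np.ndarray, dict[int, str]]:
    """Mutable 0-based positions and per-position substitution alphabets.

    Signal motifs and the insertion are protected; HR core (a/d) slots
    substitute conservatively among hydrophobics, HR non-core among polars.
    """
    seq = arch["sequence"]
    coords = arch["coords"]
    protected = set()
    for name in ("NLS", "NES", "AHA", "insertion"):
        if name in coords:
            s, e = coords[name]
            protected.update(range(s - 1, e))
    pools: dict[int, str] = {}
    hra_start = coords["HRA"][0]
    for name in ("HRA", "HRB"):
        s, e = coords[name]
        for p in range(s - 1, e):
            slot = (p - (hra_start - 1)) % 7
            pools[p] = _CORE_AA if slot in (0, 3) else _POLAR
    # the linker stays free of hydrophobic-core residues so the measured
    # HR-A boundary (and hence the linker length) is unambiguous
    for p in range(coords["DBD"][1], hra_start - 1):
        pools[p] = _NOCOIL
    mutable = np.array([i for i in range(len(seq)) if i not in protected])
    return mutable, pools


def _mutate(sequence: str, n_subs: int, mutable: np.ndarray,
            pools: Mapping[int, str], rng: np.random.Generator) -> str:
    """Substitute exactly ``n_subs`` mutable positions (no indels)."""
    n_subs = min(n_subs, mutable.size)
    sites = rng.choice(mutable, size=n_subs, replace=False)
    seq = list(sequence)
    for i in sorted(int(s) for s in sites):
        pool = [c for c in pools.get(i, AA20) if c != seq[i]]
        if not pool:
            continue
        seq[i] = pool[rng.integers(len(pool))]
    return "".join(seq)


# ---------------------------------------------------------------------------
# dataset


@dataclass
class Dataset:
    """In-memory synthetic dataset plus truth manifest."""

    config: GeneratorConfig
    proteins: list[ProteinRecord]
    queries: list[ProteinRecord]
    ancestors: list[ProteinRecord]
    gene_models: dict[str, GeneModel]
    cds: dict[str, str]
    ests: dict[str, str]
    reference_proteome: list[ProteinRecord]
    reference_edges: list[tuple[str, str]]
    annotation: dict[str, list[str]]
    universe: list[str]
    manifest: dict
    fpkm: pd.DataFrame
    ct: pd.DataFrame

    @property
    def family_ids(self) -> list[str]:
        return sorted(self.manifest["genes"])

    def protein(self, gene_id: str) -> ProteinRecord:
        for p in self.proteins:
            if p.id == gene_id:
                return p
        raise KeyError(gene_id)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.fasta")
        write_fasta(self.queries, outdir / "queries.fasta")
        write_fasta(self.ancestors, outdir / "ancestors.fasta")
        write_fasta(self.reference_proteome, outdir / "reference_proteome.fasta")
        write_fasta(_NucRecords(sorted(self.cds.items())), outdir / "cds.fasta")
        write_fasta(_NucRecords(sorted(self.ests.items())), outdir / "ests.fasta")
        rows = []
        for gid in sorted(self.gene_models):
            gm = self.gene_models[gid]
            rows.append({
                "id": gm.id, "scaffold_label": gm.scaffold_label,
                "start": gm.start, "end": gm.end, "exons": gm.exons,
                "introns": gm.introns, "est_count": gm.est_count,
            })
        pd.DataFrame(rows).to_csv(outdir / "gene_models.tsv", sep="\t", index=False)
        pd.DataFrame(self.reference_edges, columns=["gene_a", "gene_b"]).to_csv(
            outdir / "reference_edges.tsv", sep="\t", index=False)
        ann_rows = [
            {"term": t, "gene": g} for t in sorted(self.annotation)
            for g in self.annotation[t]
        ]
        pd.DataFrame(ann_rows).to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        self.fpkm.to_csv(outdir / "fpkm.tsv", sep="\t")
        self.ct.to_csv(outdir / "ct.tsv", sep="\t", index=False)


class _NucRecords:
    """Adapter giving (id, sequence) pairs the record interface write_fasta
    expects, bypassing protein alphabet checks."""

    def __init__(self, items):
        self._items = items

    def __iter__(self):
        for gid, seq in self._items:
            yield type("Rec", (), {"id": gid, "sequence": seq})()


# ---------------------------------------------------------------------------
# generation


def generate_proteome(config: GeneratorConfig | None = None) -> Dataset:
    """Generate the full synthetic dataset (proteome, gene models, ESTs,
    reference network and expression tables) with its truth manifest."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    child_prot, child_expr = ss.spawn(2)
    rng = np.random.default_rng(child_prot)
    b = _Builder(rng)

    # --- group plan
    kinds = _allocate_classes(cfg)
    subclass_cycle = {c: 0 for c in _SUBCLASSES}
    groups: list[dict] = []
    for kind, cls in kinds:
        roster = _SUBCLASSES[cls]
        sub = roster[subclass_cycle[cls] % len(roster)]
        subclass_cycle[cls] += 1
        groups.append({"kind": kind, "class": cls, "subclass": sub})
    dup_edges = _plan_duplications(cfg, groups)

    # --- chromosome plan
    pair_subsets = [("A", "B"), ("A", "D"), ("B", "D")]
    single_subs = ["A", "B", "D"]
    arms = ["L", "L", "S"]
    for idx, grp in enumerate(groups):
        grp["chrom_group"] = idx % 7 + 1
        grp["arm"] = arms[idx % 3]
        if grp["kind"] == "triad":
            grp["subgenomes"] = ["A", "B", "D"]
        elif grp["kind"] == "pair":
            grp["subgenomes"] = list(pair_subsets[idx % 3])
        else:
            grp["subgenomes"] = [single_subs[idx % 3]]
    for edge in dup_edges:
        src, dst = groups[edge["src"]], groups[edge["dst"]]
        if edge["mode"] == "same_chromosome":
            # identical chromosome token: same group, subgenome and arm
            dst["chrom_group"] = src["chrom_group"]
            dst["subgenomes"] = list(src["subgenomes"])
            dst["arm"] = src["arm"]
        elif dst["chrom_group"] == src["chrom_group"]:
            dst["chrom_group"] = dst["chrom_group"] % 7 + 1

    # --- class templates, then group ancestors (family-wide homology);
    # duplicate targets derive from their source group's ancestor
    templates = {
        cls: _build_architecture(b, cls)
        for cls, n in sorted(cfg.class_counts.items()) if n > 0
    }
    for grp in groups:
        grp["arch"] = None
    order = list(range(len(groups)))
    dst_of = {e["dst"]: e for e in dup_edges}
    for idx in order:
        if idx in dst_of:
            continue
        groups[idx]["arch"] = _derive_architecture(
            b, templates[groups[idx]["class"]], cfg.intra_class_divergence,
            fresh_linker=True)
    for idx in order:
        if idx not in dst_of:
            continue
        src_arch = groups[dst_of[idx]["src"]]["arch"]
        groups[idx]["arch"] = _derive_architecture(
            b, src_arch, cfg.duplicate_divergence, fresh_linker=False)

    # --- members
    genes: dict[str, dict] = {}
    proteins: list[ProteinRecord] = []
    gene_models: dict[str, GeneModel] = {}
    scaffold_no = 100000
    gene_no = 0
    for gi, grp in enumerate(groups):
        grp["id"] = f"HG{gi + 1:03d}"
        grp["members"] = {}
        arch = grp["arch"]
        mutable, pools = _mutation_targets(arch)
        n_sub = int(round(cfg.homoeolog_divergence * len(arch["sequence"])))
        arm = grp["arm"]
        for sub in grp["subgenomes"]:
            gene_no += 1
            gid = f"hsf{gene_no:03d}"
            seq = _mutate(arch["sequence"], n_sub, mutable, pools, rng)
            proteins.append(ProteinRecord(gid, seq))
            token = f"{grp['chrom_group']}{sub}{arm}"
            scaffold_no += int(rng.integers(1, 50))
            start = int(rng.integers(1000, 200001))
            span = int(len(seq) * 3 * rng.uniform(1.2, 2.5))
            exons = int(rng.integers(1, 6))
            gene_models[gid] = GeneModel(
                id=gid,
                chromosome=ChromosomeAssignment(grp["chrom_group"], sub, arm),
                scaffold_label=f"scaffold_{scaffold_no}_{token}",
                start=start, end=start + span,
                exons=exons, introns=exons - 1,
            )
            genes[gid] = {
                "class": grp["class"],
                "subclass": grp["subclass"],
                "group": grp["id"],
                "chromosome": {
                    "token": token,
                    "scaffold_label": gene_models[gid].scaffold_label,
                    "start": start, "end": start + span,
                },
                "domains": {k: list(v) for k, v in arch["coords"].items()},
                "linker_len": arch["linker_len"],
                "insertion_len": arch["insertion_len"],
            }
            grp["members"][sub] = gid

    # --- decoys
    decoys: dict[str, str] = {}
    decoy_models = {}
    for i in range(cfg.n_decoys_no_dbd):
        did = f"decoy_dbdless_{i + 1:02d}"
        seq = (b.background(int(rng.integers(20, 51)))
               + b.heptad_block(2 * _HEPTADS_PER_BLOCK)
               + b.background(int(rng.integers(150, 251))))
        proteins.append(ProteinRecord(did, seq))
        decoys[did] = "no_dbd"
    for i in range(cfg.n_decoys_no_coil):
        did = f"decoy_coilless_{i + 1:02d}"
        seq = (b.background(int(rng.integers(20, 51)))
               + b.dbd(0.35)
               + b.background(int(rng.integers(200, 301)), _NOCOIL))
        proteins.append(ProteinRecord(did, seq))
        decoys[did] = "no_coil"
    for did in sorted(decoys):
        seq_len = len(next(p for p in proteins if p.id == did))
        cg = int(rng.integers(1, 8))
        sub = single_subs[int(rng.integers(3))]
        token = f"{cg}{sub}L"
        scaffold_no += int(rng.integers(1, 50))
        start = int(rng.integers(1000, 200001))
        decoy_models[did] = GeneModel(
            id=did,
            chromosome=ChromosomeAssignment(cg, sub, "L"),
            scaffold_label=f"scaffold_{scaffold_no}_{token}",
            start=start, end=start + seq_len * 3,
            exons=1, introns=0,
        )
    gene_models.update(decoy_models)

    # --- queries: known Hsfs from related species, one per planted class,
    # derived from the class templates at query_divergence
    queries = []
    for cls in sorted(templates):
        arch = _derive_architecture(b, templates[cls], cfg.query_divergence,
                                    fresh_linker=True)
        queries.append(ProteinRecord(f"query_{cls}", arch["sequence"]))

    # --- ancestors as labeled subclass references
    ancestors = [
        ProteinRecord(f"anc_{grp['id']}", grp["arch"]["sequence"])
        for grp in groups
    ]
    reference_subclasses = {f"anc_{grp['id']}": grp["subclass"] for grp in groups}

    # --- CDS and ESTs
    codon_tables = _codon_choices()
    cds = {}
    for prot in proteins:
        if prot.id in decoys:
            continue
        cds[prot.id] = _reverse_translate(prot.sequence, codon_tables, rng)
    family_sorted = sorted(cds)
    if cfg.est_per_gene is not None:
        est_counts = {g: int(cfg.est_per_gene.get(g, 0)) for g in family_sorted}
    else:
        est_counts = {
            g: int(rng.integers(1, cfg.est_max + 1)) for g in family_sorted
        }
        for g in family_sorted[-cfg.n_unsupported:] if cfg.n_unsupported else []:
            est_counts[g] = 0
    ests = {}
    for g in family_sorted:
        seq = cds[g]
        for k in range(est_counts[g]):
            length = min(len(seq), 150 + int(rng.integers(0, 251)))
            start = int(rng.integers(0, len(seq) - length + 1))
            ests[f"est_{g}_{k + 1:02d}"] = seq[start:start + length]
        genes[g]["est_count"] = est_counts[g]
        gene_models[g].est_count = est_counts[g]

    # --- reference interactome with planted orthologs
    ortho_genes = []
    for grp in groups[:cfg.n_orthologs]:
        first_sub = sorted(grp["members"])[0]
        ortho_genes.append(grp["members"][first_sub])
    orthologs = {}
    reference = []
    for i, g in enumerate(ortho_genes):
        rid = f"ath{i + 1:03d}"
        prot = next(p for p in proteins if p.id == g)
        n = int(round(cfg.ortholog_divergence * len(prot)))
        mutable = np.arange(len(prot))
        seq = _mutate(prot.sequence, n, mutable, {}, rng)
        reference.append(ProteinRecord(rid, seq))
        orthologs[g] = rid
    for i in range(cfg.n_reference_decoys):
        reference.append(
            ProteinRecord(f"athx{i + 1:02d}", b.background(300)))

    n_ortho = max(len(ortho_genes), 1)
    q, r = divmod(cfg.network_edges_total, n_ortho)
    degrees = [q + 1] * r + [q] * (n_ortho - r)
    reference_edges = []
    partner_no = 0
    degree_truth = {}
    for g, deg in zip(ortho_genes, degrees):
        degree_truth[g] = deg
        for _ in range(deg):
            partner_no += 1
            reference_edges.append((orthologs[g], f"ptn{partner_no:04d}"))
    partners = [f"ptn{i + 1:04d}" for i in range(partner_no)]
    universe = partners + [f"bg{i + 1:04d}" for i in range(200)]
    annotation: dict[str, list[str]] = {}
    if partners:
        n_enriched = max(1, len(partners) // 8)
        annotation["T01_stress_response"] = partners[:n_enriched]
        for t in range(2, 9):
            picked = rng.choice(universe, size=min(40, len(universe)),
                                replace=False)
            annotation[f"T{t:02d}_term"] = sorted(str(x) for x in picked)

    # --- expression (independent child stream)
    fpkm, ct, ct_effects = _generate_expression_tables(cfg, family_sorted,
                                                       child_expr)

    manifest = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "genes": genes,
        "decoys": decoys,
        "groups": {
            grp["id"]: {
                "kind": grp["kind"], "class": grp["class"],
                "subclass": grp["subclass"], "chrom_group": grp["chrom_group"],
                "members": grp["members"],
            } for grp in groups
        },
        "duplications": sorted(
            (
                {
                    "groups": sorted((groups[e["src"]]["id"],
                                      groups[e["dst"]]["id"])),
                    "mode": e["mode"],
                }
                for e in dup_edges
            ),
            key=lambda d: d["groups"],
        ),
        "orthologs": orthologs,
        "network": {
            "edges_total": int(sum(degrees)) if ortho_genes else 0,
            "degrees": degree_truth,
        },
        "ct_effects": ct_effects,
        "est_counts": est_counts,
        "queries": [p.id for p in queries],
        "reference_subclasses": reference_subclasses,
    }
    _check_manifest(manifest, proteins)

    return Dataset(
        config=cfg, proteins=proteins, queries=queries, ancestors=ancestors,
        gene_models=gene_models, cds=cds, ests=ests,
        reference_proteome=reference, reference_edges=reference_edges,
        annotation=annotation, universe=universe, manifest=manifest,
        fpkm=fpkm, ct=ct,
    )


def generate_expression(config: GeneratorConfig | None = None,
                        gene_ids: Sequence[str] | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM and Ct tables only (same values as the full dataset's)."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    if gene_ids is None:
        gene_ids = [f"hsf{i + 1:03d}" for i in range(cfg.family_size)]
    _, child_expr = np.random.SeedSequence(cfg.seed).spawn(2)
    fpkm, ct, _ = _generate_expression_tables(cfg, sorted(gene_ids), child_expr)
    return fpkm, ct


def _generate_expression_tables(cfg: GeneratorConfig, gene_ids: list[str],
                                seed) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    rng = np.random.default_rng(seed)
    samples = [f"{t}_r{r + 1}" for t in cfg.tissues
               for r in range(cfg.fpkm_replicates)]
    values = np.empty((len(gene_ids), len(samples)))
    for i, g in enumerate(gene_ids):
        base = rng.lognormal(mean=np.log(20.0), sigma=1.0)
        for j_t, tissue in enumerate(cfg.tissues):
            effect = rng.lognormal(mean=0.0, sigma=0.7)
            for r in range(cfg.fpkm_replicates):
                noise = (rng.lognormal(0.0, cfg.fpkm_dispersion)
                         if cfg.fpkm_dispersion > 0 else 1.0)
                values[i, j_t * cfg.fpkm_replicates + r] = base * effect * noise
    fpkm = pd.DataFrame(np.round(values, 3), index=gene_ids, columns=samples)
    fpkm.index.name = "gene"

    if cfg.ct_effects is not None:
        ct_effects = {g: float(f) for g, f in cfg.ct_effects.items()}
    else:
        default_folds = [3.2, 2.5, 4.1, 2.9, 3.6, 2.2, 5.0, 2.7,
                         0.45, 0.30, 0.52, 0.38, 0.25]
        chosen = gene_ids[:len(default_folds)]
        ct_effects = dict(zip(chosen, default_folds))
    rows = []
    for cond in (cfg.control_condition, cfg.treated_condition):
        for r in range(cfg.ct_replicates):
            noise = rng.normal(0.0, cfg.ct_noise_sd) if cfg.ct_noise_sd > 0 else 0.0
            rows.append({"gene": cfg.reference_gene, "condition": cond,
                         "replicate": r + 1, "ct": 18.0 + noise})
    base_ct = {}
    for g in sorted(ct_effects):
        base_ct[g] = 24.0 + float(rng.uniform(-2.0, 2.0))
    for g in sorted(ct_effects):
        fold = ct_effects[g]
        for cond, shift in ((cfg.control_condition, 0.0),
                            (cfg.treated_condition, -np.log2(fold))):
            for r in range(cfg.ct_replicates):
                noise = (rng.normal(0.0, cfg.ct_noise_sd)
                         if cfg.ct_noise_sd > 0 else 0.0)
                rows.append({"gene": g, "condition": cond, "replicate": r + 1,
                             "ct": base_ct[g] + shift + noise})
    ct = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
    return fpkm, ct, ct_effects


def _codon_choices() -> dict[str, list[str]]:
    from Bio.Data.CodonTable import standard_dna_table
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(standard_dna_table.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


def _reverse_translate(protein: str, codons: Mapping[str, list[str]],
                       rng: np.random.Generator) -> str:
    out = []
    for aa in protein:
        choices = codons[aa]
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _check_manifest(manifest: dict, proteins: Sequence[ProteinRecord]) -> None:
    """Internal invariants: unique ids, in-bounds coordinates, DBD before
    HR-A/B, group accounting."""
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise AssertionError("duplicate sequence ids emitted")
    by_id = {p.id: p for p in proteins}
    for gid, info in manifest["genes"].items():
        seq = by_id[gid].sequence
        for name, (s, e) in info["domains"].items():
            if not 1 <= s <= e <= len(seq):
                raise AssertionError(f"{gid}: {name} span out of bounds")
        if info["domains"]["DBD"][1] >= info["domains"]["HRAB"][0]:
            raise AssertionError(f"{gid}: DBD must precede HR-A/B")
    kinds = [g["kind"] for g in manifest["groups"].values()]
    total = (3 * kinds.count("triad") + 2 * kinds.count("pair")
             + kinds.count("singleton"))
    if total != len(manifest["genes"]):
        raise AssertionError("group accounting does not match family size")
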