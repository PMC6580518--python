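"""End-to-end orchestration: screen -> scan -> classify -> phylo ->
genome organization -> network -> expression, with deterministic outputs
and a machine-readable summary.

Thresholds default to the survey's stated values (E <= 1e-5, identity >=
50% for screening; strict >80/>80 for duplications; 1000 bootstrap
replicates; enrichment alpha 0.01; differential-expression alpha 0.05).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import domains, expression, genome, homology, network, phylo
from .seqcore import GeneModel, ProteinRecord, summarize_family
from .simulate import Dataset, GeneratorConfig, generate_proteome


@dataclass
class PipelineConfig:
    """Thresholds, seed and stage toggles for a pipeline run."""

    e_max: float = 1e-5
    id_min: float = 50.0
    dup_identity: float = 80.0
    dup_coverage: float = 80.0
    bootstrap_reps: int = 1000
    enrichment_alpha: float = 0.01
    de_alpha: float = 0.05
    est_id_min: float = 95.0
    est_len_min: int = 100
    seed: int = 0
    run_phylo: bool = True
    run_genome: bool = True
    run_network: bool = True
    run_expression: bool = True

    def validate(self) -> None:
        for name in ("id_min", "dup_identity", "dup_coverage", "est_id_min"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")
        for name in ("enrichment_alpha", "de_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be a probability")
        if self.e_max <= 0 or self.bootstrap_reps < 0:
            raise ValueError("invalid e_max or bootstrap_reps")


def run_pipeline(
    dataset: Dataset,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run all enabled stages on a dataset and return the summary dict.

    With ``outdir`` set, per-stage reports (TSV), the tree (Newick), link
    tables and ``summary.json`` are written there.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "thresholds": asdict(cfg)}

    # --- screening
    candidates, hits = homology.screen_candidates(
        dataset.proteins, dataset.gene_models, dataset.queries,
        e_max=cfg.e_max, id_min=cfg.id_min,
    )
    summary["screen"] = {"n_input": len(dataset.proteins),
                         "n_candidates": len(candidates)}
    if out:
        pd.DataFrame([vars(h) for h in hits]).to_csv(
            out / "screen_report.tsv", sep="\t", index=False)

    # --- EST support
    est_counts = homology.assign_ests(
        {g: dataset.cds[g] for g in candidates if g in dataset.cds},
        dataset.ests, id_min=cfg.est_id_min, len_min=cfg.est_len_min)
    for gid, n in est_counts.items():
        if gid in dataset.gene_models:
            dataset.gene_models[gid].est_count = n
    summary["est"] = {
        "n_supported": sum(1 for v in est_counts.values() if v > 0),
        "n_unsupported": sum(1 for v in est_counts.values() if v == 0),
    }

    # --- domain scan and architecture
    architectures: dict[str, domains.HsfArchitecture] = {}
    incomplete: list[str] = []
    by_id = {p.id: p for p in dataset.proteins}
    for gid in candidates:
        arch = scan_architecture(by_id[gid])
        if arch is None:
            incomplete.append(gid)
        else:
            arch.signals = domains.find_signal_motifs(by_id[gid])
            architectures[gid] = arch
    family = sorted(architectures)
    summary["scan"] = {"n_complete": len(family), "n_incomplete": len(incomplete)}
    if out:
        _write_architecture_reports(architectures, by_id, out)

    # --- classification
    calls = [_classify.assign_class(architectures[g], g) for g in family]
    fam = _classify.classify_family(calls)
    summary["classify"] = {
        "counts": fam.counts,
        "n_flagged": sum(1 for c in calls if c.flags),
    }
    if out:
        pd.DataFrame([
            {"id": c.gene_id, "class": c.hsf_class, "insertion": c.insertion_len,
             "linker": c.linker_len, "flags": ",".join(sorted(c.flags))}
            for c in calls
        ]).to_csv(out / "classification.tsv", sep="\t", index=False)

    # --- phylogeny and subclass labeling
    if cfg.run_phylo and len(family) >= 3:
        regions = [
            ProteinRecord(g, _n_proximal(by_id[g], architectures[g]))
            for g in family
        ]
        ref_labels = dataset.manifest.get("reference_subclasses", {})
        for anc in dataset.ancestors:
            arch = scan_architecture(anc)
            if arch is not None:
                regions.append(ProteinRecord(anc.id, _n_proximal(anc, arch)))
        aln = phylo.align_family(regions)
        tree = phylo.nj_from_alignment(aln, clamp=True)
        tree = phylo.bootstrap_support(aln, n_reps=cfg.bootstrap_reps,
                                       seed=cfg.seed, tree=tree)
        subclasses = (
            phylo.label_subclasses(tree, ref_labels) if ref_labels else {}
        )
        summary["phylo"] = {
            "n_taxa": len(aln.ids),
            "n_labeled": len(subclasses),
        }
        if out:
            (out / "family.nwk").write_text(tree.newick() + "\n")
            pd.DataFrame(sorted(subclasses.items()),
                         columns=["id", "subclass"]).to_csv(
                out / "subclasses.tsv", sep="\t", index=False)
    else:
        subclasses = {}

    # --- genome organization
    if cfg.run_genome:
        fam_models = {g: dataset.gene_models[g] for g in family}
        cache = homology.PairwiseCache({g: by_id[g] for g in family})
        groups, grouping = genome.group_homoeologs(
            fam_models, cache, id_min=cfg.dup_identity, cov_min=cfg.dup_coverage)
        dups = genome.find_duplicates(
            fam_models, cache, groups,
            id_min=cfg.dup_identity, cov_min=cfg.dup_coverage)
        collapsed = genome.collapse_duplicate_pairs(dups, groups)
        dist = genome.distribution_report(fam_models.values())
        summary["genome"] = {
            "n_triads": grouping.n_triads,
            "n_pairs": grouping.n_pairs,
            "n_singletons": grouping.n_singletons,
            "family_size": grouping.family_size,
            "n_dup_pairs": len(collapsed),
            "n_dup_same_chromosome": sum(
                1 for d in collapsed if d.mode == "same_chromosome"),
            "n_dup_segmental": sum(
                1 for d in collapsed if d.mode == "segmental"),
            "distribution": dist,
        }
        if out:
            (out / "links.txt").write_text(
                "\n".join(genome.export_links(groups, collapsed, fam_models))
                + "\n")
            pd.DataFrame([
                {"group": g.group_id, "kind": g.kind,
                 "chrom_group": g.chrom_group,
                 "members": ",".join(g.gene_ids)}
                for g in groups
            ]).to_csv(out / "homoeolog_groups.tsv", sep="\t", index=False)
            pd.DataFrame([vars(d) for d in collapsed]).to_csv(
                out / "duplications.tsv", sep="\t", index=False)

    # --- network projection and enrichment
    if cfg.run_network and dataset.reference_proteome:
        fam_prots = [by_id[g] for g in family]
        orthomap = network.map_orthologs(
            fam_prots, dataset.reference_proteome,
            e_max=cfg.e_max, id_min=cfg.id_min)
        projected = network.project_network(orthomap, dataset.reference_edges)
        interacting = sorted({p for _, p in projected.edges})
        enrich = (
            network.hypergeom_enrich(
                [g for g in interacting if g in set(dataset.universe)],
                dataset.annotation, dataset.universe,
                alpha=cfg.enrichment_alpha)
            if dataset.annotation else []
        )
        summary["network"] = {
            "n_mapped": len(orthomap.mapping),
            "n_edges": projected.n_edges,
            "mean_degree": projected.mean_degree,
            "n_enriched_terms": sum(1 for e in enrich if e.significant),
        }
        if out:
            pd.DataFrame(sorted(projected.edges),
                         columns=["gene", "partner"]).to_csv(
                out / "network_edges.tsv", sep="\t", index=False)
            pd.DataFrame([vars(e) for e in enrich]).to_csv(
                out / "enrichment.tsv", sep="\t", index=False)

    # --- expression
    if cfg.run_expression and not dataset.ct.empty:
        gcfg = dataset.config
        log2 = expression.log2_heatmap_matrix(dataset.fpkm)
        folds = expression.ddct_quantify(
            dataset.ct, gcfg.reference_gene, gcfg.control_condition,
            gcfg.treated_condition, alpha=cfg.de_alpha)
        summary["expression"] = {
            "n_genes_fpkm": int(log2.shape[0]),
            "n_quantified": len(folds),
            "n_significant": sum(1 for f in folds if f.significant),
            "folds": {f.gene_id: round(f.fold, 4) for f in folds},
        }
        if out:
            log2.to_csv(out / "fpkm_log2.tsv", sep="\t")
            pd.DataFrame([vars(f) for f in folds]).to_csv(
                out / "fold_changes.tsv", sep="\t", index=False)

    # --- family stats
    stats = summarize_family(
        [dataset.gene_models[g] for g in family],
        classes={c.gene_id: c.hsf_class for c in calls if c.hsf_class},
        aa_lengths={g: len(by_id[g]) for g in family},
    )
    summary["family_stats"] = stats.to_dict()
    summary["subclass_calls"] = subclasses

    if out:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def scan_architecture(protein: ProteinRecord) -> domains.HsfArchitecture | None:
    """DBD + coiled-coil scan; None when the architecture is incomplete."""
    dbd = domains.scan_dbd(protein)
    if dbd is None:
        return None
    coils = domains.scan_coiled_coil(protein)
    try:
        return domains.measure_architecture(protein, dbd, coils)
    except domains.IncompleteArchitecture:
        return None


def _n_proximal(protein: ProteinRecord, arch: domains.HsfArchitecture) -> str:
    """The conserved N-proximal region: DBD start through HR-A/B end."""
    return protein.sequence[arch.dbd.start - 1:arch.hrab.end]


def _write_architecture_reports(architectures, by_id, out: Path) -> None:
    rows = []
    gff = ["##gff-version 3"]
    for gid in sorted(architectures):
        arch = architectures[gid]
        rows.append({
            "id": gid,
            "dbd": f"{arch.dbd.start}-{arch.dbd.end}",
            "hrab": f"{arch.hrab.start}-{arch.hrab.end}",
            "linker_len": arch.linker_len,
            "insertion_len": arch.insertion_len,
            "nls": _fmt_signals(arch, "NLS"),
            "nes": _fmt_signals(arch, "NES"),
            "aha": _fmt_signals(arch, "AHA"),
        })
        for ann in [arch.dbd, arch.hrab, *arch.signals]:
            gff.append(
                "\t".join([gid, "hsfkit", ann.kind, str(ann.start),
                           str(ann.end), f"{ann.score:.2f}", ".", ".",
                           f"ID={gid}.{ann.kind}.{ann.start}"]))
    pd.DataFrame(rows).to_csv(out / "architecture.tsv", sep="\t", index=False)
    (out / "architecture.gff3").write_text("\n".join(gff) + "\n")


def _fmt_signals(arch: domains.HsfArchitecture, kind: str) -> str:
    parts = [f"({a.start}){a.snippet}" for a in arch.signals if a.kind == kind]
    return " ".join(parts) if parts else "nd"


def simulate_and_run(
    generator_config: GeneratorConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[Dataset, dict]:
    """Generate a synthetic dataset and run the pipeline on it."""
    dataset = generate_proteome(generator_config)
    summary = run_pipeline(dataset, pipeline_config, outdir)
    return dataset, summary
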