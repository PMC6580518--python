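"""Generator contracts: determinism, accounting, manifest invariants."""

import json

import pytest

from conftest import small_generator_config
from hsfkit.simulate import ConfigError, GeneratorConfig, generate_expression, generate_proteome


class TestConfigValidation:
    def test_counts_echo_config(self, full_dataset):
        counts = {c: 0 for c in "ABC"}
        for info in full_dataset.manifest["genes"].values():
            counts[info["class"]] += 1
        assert counts == {"A": 38, "B": 16, "C": 24}

    def test_group_arithmetic_small(self):
        cfg = GeneratorConfig(
            class_counts={"A": 6, "B": 2, "C": 1},
            n_triads=2, n_pairs=1, n_singletons=1,
            n_duplicate_pairs_same_chrom=0, n_duplicate_pairs_segmental=0,
            n_decoys_no_dbd=0, n_decoys_no_coil=0, n_orthologs=2,
            network_edges_total=10, seed=1)
        ds = generate_proteome(cfg)
        assert len(ds.manifest["genes"]) == 3 * 2 + 2 * 1 + 1

    def test_inconsistent_accounting_rejected(self):
        with pytest.raises(ConfigError, match="does not match"):
            GeneratorConfig(class_counts={"A": 10},
                            n_triads=1, n_pairs=1, n_singletons=1).validate()

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_decoys_no_dbd=-1).validate()

    def test_infeasible_class_partition_rejected(self):
        # one class of size 1 cannot occupy a triad
        cfg = GeneratorConfig(class_counts={"A": 1}, n_triads=1, n_pairs=0,
                              n_singletons=0, n_duplicate_pairs_same_chrom=0,
                              n_duplicate_pairs_segmental=0)
        with pytest.raises(ConfigError):
            generate_proteome(cfg)

    def test_infeasible_duplications_rejected(self):
        cfg = small_generator_config()
        cfg.n_duplicate_pairs_same_chrom = 5  # only one singleton planted
        with pytest.raises(ConfigError):
            generate_proteome(cfg)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = small_generator_config(seed=42)
        d1 = generate_proteome(cfg)
        d2 = generate_proteome(small_generator_config(seed=42))
        assert [(p.id, p.sequence) for p in d1.proteins] == \
               [(p.id, p.sequence) for p in d2.proteins]
        assert d1.cds == d2.cds and d1.ests == d2.ests
        assert json.dumps(d1.manifest, sort_keys=True) == \
               json.dumps(d2.manifest, sort_keys=True)
        assert d1.fpkm.equals(d2.fpkm) and d1.ct.equals(d2.ct)

    def test_different_seed_differs(self):
        d1 = generate_proteome(small_generator_config(seed=1))
        d2 = generate_proteome(small_generator_config(seed=2))
        assert d1.proteins[0].sequence != d2.proteins[0].sequence

    def test_expression_tables_independent_of_proteome_path(self):
        cfg = small_generator_config(seed=9)
        ds = generate_proteome(cfg)
        fpkm, ct = generate_expression(small_generator_config(seed=9),
                                       sorted(ds.manifest["genes"]))
        assert fpkm.equals(ds.fpkm) and ct.equals(ds.ct)

    def test_write_round_trip(self, small_dataset, tmp_path):
        small_dataset.write(tmp_path)
        from hsfkit.seqcore import read_fasta, read_gene_models
        prots = read_fasta(tmp_path / "proteins.fasta")
        assert [(p.id, p.sequence) for p in prots] == \
               [(p.id, p.sequence) for p in small_dataset.proteins]
        models = read_gene_models(tmp_path / "gene_models.tsv")
        assert len(models) == len(small_dataset.gene_models)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["genes"].keys() == small_dataset.manifest["genes"].keys()


class TestManifestInvariants:
    def test_every_id_unique_and_coords_in_bounds(self, small_dataset):
        ds = small_dataset
        ids = [p.id for p in ds.proteins]
        assert len(ids) == len(set(ids))
        for gid, info in ds.manifest["genes"].items():
            seq = ds.protein(gid).sequence
            for name, (s, e) in info["domains"].items():
                assert 1 <= s <= e <= len(seq)
            assert info["domains"]["DBD"][1] < info["domains"]["HRAB"][0]

    def test_linker_lengths_inside_class_ranges(self, small_dataset):
        from hsfkit.classify import LINKER_RANGES
        for info in small_dataset.manifest["genes"].values():
            lo, hi = LINKER_RANGES[info["class"]]
            assert lo <= info["linker_len"] <= hi

    def test_insertion_lengths_per_class(self, small_dataset):
        want = {"A": 21, "B": 0, "C": 7}
        for info in small_dataset.manifest["genes"].values():
            assert info["insertion_len"] == want[info["class"]]

    def test_same_chromosome_duplicates_share_token(self, full_dataset):
        ds = full_dataset
        for dup in ds.manifest["duplications"]:
            g1, g2 = dup["groups"]
            m1 = sorted(ds.manifest["groups"][g1]["members"].values())
            m2 = sorted(ds.manifest["groups"][g2]["members"].values())
            tokens1 = {ds.manifest["genes"][m]["chromosome"]["token"] for m in m1}
            tokens2 = {ds.manifest["genes"][m]["chromosome"]["token"] for m in m2}
            if dup["mode"] == "same_chromosome":
                assert tokens1 == tokens2
            else:
                assert not tokens1 & tokens2


class TestExpressionGeneration:
    def test_zero_dispersion_gives_equal_replicates(self):
        cfg = small_generator_config(seed=5)
        cfg.fpkm_dispersion = 0.0
        ds = generate_proteome(cfg)
        for tissue in cfg.tissues:
            cols = [c for c in ds.fpkm.columns if c.startswith(tissue)]
            sub = ds.fpkm[cols]
            assert (sub.nunique(axis=1) == 1).all()

    def test_fpkm_non_negative(self, small_dataset):
        assert (small_dataset.fpkm.to_numpy() >= 0).all()

    def test_ct_has_reference_and_replicates(self, small_dataset):
        ct = small_dataset.ct
        for cond in ("H17CK", "H17Cd"):
            ref = ct[(ct.gene == "actin") & (ct.condition == cond)]
            assert len(ref) == 3
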