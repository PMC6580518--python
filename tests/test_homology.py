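"""Local alignment, E-values, the screening filter chain and EST support."""

import itertools

import numpy as np
import pytest

from hsfkit import homology
from hsfkit.homology import (
    AlignmentResult,
    ScoringScheme,
    est_support,
    evalue,
    local_align,
    screen_candidates,
)
from hsfkit.seqcore import GeneModel, ProteinRecord, parse_chromosome_label

SIMPLE = ScoringScheme(match=1.0, mismatch=-1.0, gap_open=0.0, gap_extend=1.0)


def oracle_local_score(a: str, b: str, match: float, mismatch: float,
                       gap: float) -> float:
    """Exhaustive enumeration of local alignments under linear gap costs.

    Every order-preserving pairing of positions is scored as the sum of
    match/mismatch terms minus gap * (unaligned positions inside each
    aligned span). Independent of any dynamic-programming recurrence.
    """
    best = 0.0
    n, m = len(a), len(b)
    for k in range(1, min(n, m) + 1):
        for ii in itertools.combinations(range(n), k):
            for jj in itertools.combinations(range(m), k):
                subst = sum(
                    match if a[i] == b[j] else mismatch for i, j in zip(ii, jj)
                )
                gaps = (ii[-1] - ii[0] + 1 - k) + (jj[-1] - jj[0] + 1 - k)
                best = max(best, subst - gap * gaps)
    return best


class TestLocalAlignment:
    def test_worked_linear_gap_example(self):
        res = local_align(ProteinRecord("a", "AAG"), ProteinRecord("b", "AG"),
                          SIMPLE)
        assert res.score == 2.0
        assert oracle_local_score("AAG", "AG", 1, -1, 1) == 2.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        letters = list("ACDE")
        for _ in range(40):
            a = "".join(rng.choice(letters, size=int(rng.integers(1, 7))))
            b = "".join(rng.choice(letters, size=int(rng.integers(1, 7))))
            got = local_align(ProteinRecord("a", a), ProteinRecord("b", b),
                              SIMPLE).score
            assert got == pytest.approx(oracle_local_score(a, b, 1, -1, 1))

    def test_self_alignment_is_perfect(self):
        p = ProteinRecord("p", "MKVLDEWFRAY")
        res = local_align(p, p)
        assert res.identity_pct == 100.0
        assert res.coverage_longer_pct == 100.0

    def test_score_symmetry(self):
        rng = np.random.default_rng(23)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(letters, size=30))
            b = "".join(rng.choice(letters, size=25))
            ra = local_align(ProteinRecord("a", a), ProteinRecord("b", b))
            rb = local_align(ProteinRecord("b", b), ProteinRecord("a", a))
            assert ra.score == rb.score

    def test_alignment_result_invariants(self):
        with pytest.raises(ValueError):
            AlignmentResult("a", "b", 1.0, 5, 6, 120.0, 50.0, 1.0)


class TestEvalue:
    def test_linear_in_database_size(self):
        s = ScoringScheme()
        assert evalue(50, 100, 200, s) == pytest.approx(
            2 * evalue(50, 100, 100, s))

    def test_decreasing_in_score_and_limit(self):
        s = ScoringScheme()
        es = [evalue(x, 100, 100, s) for x in (10, 50, 200, 2000)]
        assert es == sorted(es, reverse=True)
        assert es[-1] < 1e-200

    def test_direct_value(self):
        s = ScoringScheme(lam=0.267, k=0.041)
        assert evalue(50, 100, 100, s) == pytest.approx(
            0.041 * 1e4 * np.exp(-13.35))


def _make_gene(gid, label, start, end):
    return GeneModel(gid, parse_chromosome_label(label), label, start, end)


class TestScreening:
    def test_recovers_exactly_the_planted_family(self, small_dataset):
        ds = small_dataset
        cands, hits = screen_candidates(ds.proteins, ds.gene_models, ds.queries)
        assert cands == sorted(ds.manifest["genes"])

    def test_precision_and_recall_one(self, small_dataset):
        ds = small_dataset
        cands, _ = screen_candidates(ds.proteins, ds.gene_models, ds.queries)
        truth = set(ds.manifest["genes"])
        assert set(cands) == truth  # precision = recall = 1.0

    def test_relaxing_thresholds_never_shrinks(self, small_dataset):
        ds = small_dataset
        strict, _ = screen_candidates(ds.proteins, ds.gene_models, ds.queries,
                                      e_max=1e-5, id_min=50.0)
        loose, _ = screen_candidates(ds.proteins, ds.gene_models, ds.queries,
                                     e_max=1e-2, id_min=30.0)
        assert set(strict) <= set(loose)

    def test_overlapping_isoforms_keep_longest(self, small_dataset):
        ds = small_dataset
        gid = sorted(ds.manifest["genes"])[0]
        prot = ds.protein(gid)
        iso = ProteinRecord("aaa_iso", prot.sequence[:-40])  # shorter isoform
        gm = ds.gene_models[gid]
        models = dict(ds.gene_models)
        models["aaa_iso"] = _make_gene("aaa_iso", gm.scaffold_label,
                                       gm.start + 5, gm.end - 5)
        cands, _ = screen_candidates(list(ds.proteins) + [iso], models,
                                     ds.queries)
        assert gid in cands and "aaa_iso" not in cands

    def test_empty_query_set_warns(self, small_dataset):
        ds = small_dataset
        with pytest.warns(UserWarning):
            cands, hits = screen_candidates(ds.proteins, ds.gene_models, [])
        assert cands == []


class TestEstSupport:
    def test_empty_est_set_unsupported(self):
        count, status = est_support("ATGC" * 100, [])
        assert (count, status) == (0, "unsupported")

    def test_exact_substrings_counted(self):
        cds = "ATGCGTTATCCG" * 40
        ests = [cds[10:210], cds[50:300], cds[0:150]]
        count, status = est_support(cds, ests)
        assert (count, status) == (3, "supported")

    def test_short_or_foreign_ests_excluded(self):
        rng = np.random.default_rng(9)
        cds = "".join(rng.choice(list("ACGT"), size=600))
        foreign = "".join(rng.choice(list("ACGT"), size=300))
        count, _ = est_support(cds, [cds[:50], foreign])
        assert count == 0

    def test_manifest_est_counts_recovered(self, small_dataset):
        ds = small_dataset
        counts = homology.assign_ests(ds.cds, ds.ests)
        assert counts == ds.manifest["est_counts"]
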