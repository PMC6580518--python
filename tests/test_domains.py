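"""DBD profile scan, coiled-coil detection, architecture measurement and
signal motifs."""

import numpy as np
import pytest

from hsfkit import domains
from hsfkit.domains import (
    DomainAnnotation,
    IncompleteArchitecture,
    find_signal_motifs,
    measure_architecture,
    scan_coiled_coil,
    scan_dbd,
)
from hsfkit.pipeline import scan_architecture
from hsfkit.seqcore import ProteinRecord


def _ideal_heptads(n: int, rng) -> str:
    out = []
    for _ in range(n):
        for slot in range(7):
            pool = "LI" if slot == 0 else ("LVM" if slot == 3 else "EKQASNR")
            out.append(pool[rng.integers(len(pool))])
    return "".join(out)


class TestDbdScan:
    def test_planted_dbd_recovered_within_two_residues(self, small_dataset):
        ds = small_dataset
        for gid, info in sorted(ds.manifest["genes"].items()):
            hit = scan_dbd(ds.protein(gid))
            assert hit is not None
            s, e = info["domains"]["DBD"]
            assert abs(hit.start - s) <= 2 and abs(hit.end - e) <= 2

    def test_shuffled_sequences_rarely_hit(self, small_dataset):
        ds = small_dataset
        seq = ds.protein(sorted(ds.manifest["genes"])[0]).sequence
        rng = np.random.default_rng(41)
        letters = np.array(list(seq))
        hits = 0
        for _ in range(1000):
            rng.shuffle(letters)
            if scan_dbd(ProteinRecord("s", "".join(letters))) is not None:
                hits += 1
        assert hits / 1000 < 0.01

    def test_sequence_shorter_than_profile(self):
        assert scan_dbd(ProteinRecord("s", "MKV")) is None

    def test_snippet_round_trip(self, small_dataset):
        ds = small_dataset
        p = ds.protein(sorted(ds.manifest["genes"])[0])
        hit = scan_dbd(p)
        assert hit.snippet == p.sequence[hit.start - 1:hit.end]


class TestCoiledCoil:
    def test_ideal_heptad_repeat_detected(self):
        rng = np.random.default_rng(7)
        coil = _ideal_heptads(6, rng)  # 42 residues
        seq = "".join(rng.choice(list("PGSTNQDE"), size=30)) + coil + \
            "".join(rng.choice(list("PGSTNQDE"), size=30))
        segments = scan_coiled_coil(ProteinRecord("c", seq))
        assert len(segments) == 1
        seg = segments[0]
        coil_span = set(range(31, 31 + 42))
        overlap = len(coil_span & set(range(seg.start, seg.end + 1)))
        assert overlap / 42 >= 0.8

    def test_polyproline_has_no_segment(self):
        assert scan_coiled_coil(ProteinRecord("p", "P" * 80)) == []

    def test_planted_hrab_recovered(self, small_dataset):
        ds = small_dataset
        for gid, info in sorted(ds.manifest["genes"].items()):
            segs = scan_coiled_coil(ds.protein(gid))
            s, e = info["domains"]["HRAB"]
            planted = set(range(s, e + 1))
            assert any(planted & set(range(x.start, x.end + 1)) for x in segs)

    def test_locality_of_window_scores(self):
        rng = np.random.default_rng(13)
        core = _ideal_heptads(6, rng)
        tail = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
        a = scan_coiled_coil(ProteinRecord("a", core + tail))[0]
        b = scan_coiled_coil(ProteinRecord("b", core + tail + "WWWW"))[0]
        assert (a.start, a.end) == (b.start, b.end)

    def test_annotation_invariants(self):
        with pytest.raises(ValueError):
            DomainAnnotation("DBD", 5, 3, 0.0, "x")
        with pytest.raises(ValueError):
            DomainAnnotation("DBD", 1, 3, 0.0, "toolong")


class TestArchitecture:
    def test_planted_linker_and_insertion_exact(self, small_dataset):
        ds = small_dataset
        for gid, info in sorted(ds.manifest["genes"].items()):
            arch = scan_architecture(ds.protein(gid))
            assert arch is not None, gid
            assert arch.linker_len == info["linker_len"]
            assert arch.insertion_len == info["insertion_len"]

    def test_decoys_have_no_complete_architecture(self, small_dataset):
        ds = small_dataset
        for did in sorted(ds.manifest["decoys"]):
            assert scan_architecture(ds.protein(did)) is None

    def test_no_coil_after_dbd_is_incomplete(self, small_dataset):
        ds = small_dataset
        p = ds.protein(sorted(ds.manifest["genes"])[0])
        dbd = scan_dbd(p)
        with pytest.raises(IncompleteArchitecture):
            measure_architecture(p, dbd, [])

    def test_missing_dbd_is_incomplete(self, small_dataset):
        ds = small_dataset
        p = ds.protein(sorted(ds.manifest["genes"])[0])
        with pytest.raises(IncompleteArchitecture):
            measure_architecture(p, None, scan_coiled_coil(p))

    def test_contiguous_blocks_mean_zero_insertion(self):
        rng = np.random.default_rng(3)
        # one uninterrupted 8-heptad region: a compact class-B-style HR-A/B
        seq = ("M" * 0) + _ideal_heptads(8, rng)
        p = ProteinRecord("b", "G" * 20 + seq + "G" * 20)
        segs = scan_coiled_coil(p)
        fake_dbd = domains.annotate("DBD", p.sequence, 1, 10, 50.0)
        arch = measure_architecture(p, fake_dbd, segs)
        assert arch.insertion_len == 0


class TestSignalMotifs:
    def test_basic_cluster_reported_as_nls(self):
        seq = "MAAAAAAAAKRPRAAAAAAAA"
        anns = find_signal_motifs(ProteinRecord("n", seq))
        nls = [a for a in anns if a.kind == "NLS"]
        assert len(nls) == 1 and nls[0].snippet == "KRPR"

    def test_aha_window_detected(self):
        seq = "A" * 40 + "DSFWEQFLCA" + "A" * 10
        anns = find_signal_motifs(ProteinRecord("a", seq))
        aha = [a for a in anns if a.kind == "AHA"]
        target = set(range(41, 51))
        assert any(target & set(range(x.start, x.end + 1)) for x in aha)

    def test_nes_pattern_in_c_terminal_half(self):
        seq = "A" * 40 + "LTEQMGLL" + "AAAA"
        anns = find_signal_motifs(ProteinRecord("e", seq))
        assert any(a.kind == "NES" for a in anns)

    def test_polyalanine_has_no_motifs(self):
        assert find_signal_motifs(ProteinRecord("x", "A" * 60)) == []

    def test_planted_motifs_recovered(self, small_dataset):
        ds = small_dataset
        for gid, info in sorted(ds.manifest["genes"].items()):
            anns = find_signal_motifs(ds.protein(gid))
            for kind in ("NLS", "AHA", "NES"):
                if kind not in info["domains"]:
                    continue
                s, e = info["domains"][kind]
                span = set(range(s, e + 1))
                assert any(
                    a.kind == kind and span & set(range(a.start, a.end + 1))
                    for a in anns
                ), (gid, kind)

    def test_snippets_match_coordinates(self, small_dataset):
        ds = small_dataset
        gid = sorted(ds.manifest["genes"])[0]
        p = ds.protein(gid)
        for a in find_signal_motifs(p):
            assert a.snippet == p.sequence[a.start - 1:a.end]
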