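"""Domain annotation: DBD profile scan, heptad coiled-coil detection for the
HR-A/B region, architecture measurement (linker and insertion lengths) and
signal-motif patterns (NLS, NES, AHA).

The coiled-coil scanner is a windowed heptad-propensity model: each
28-residue window is scored in all seven registers as the mean log
propensity ratio of its residues at core (a/d) versus non-core positions.
Coarse window scores locate candidate regions; within a region, HR-A and
HR-B are refined as the two maximal smoothed per-residue runs separated by
the lowest-propensity internal gap, which is what makes the inter-block
insertion length (the primary class criterion) measurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .seqcore import AA20, ProteinRecord, _load_json

_COIL = _load_json("coil_propensity.json")
_DBD = _load_json("dbd_profile.json")

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}


def _log_prop_tables() -> tuple[np.ndarray, np.ndarray]:
    ad = np.full(26, np.log(0.05))
    other = np.full(26, np.log(0.15))
    for aa, v in _COIL["ad"].items():
        ad[ord(aa) - 65] = np.log(v)
    for aa, v in _COIL["other"].items():
        other[ord(aa) - 65] = np.log(v)
    return ad, other


_LOG_AD, _LOG_OTHER = _log_prop_tables()


def _encode(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).astype(np.int64) - 65


@dataclass(frozen=True)
class DomainAnnotation:
    """A located feature: kind, 1-based inclusive span, score and snippet."""

    kind: str  # DBD | HRAB | NLS | NES | AHA
    start: int
    end: int
    score: float
    snippet: str
    register: int | None = None  # heptad frame for HRAB segments

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("invalid annotation span")
        if len(self.snippet) != self.end - self.start + 1:
            raise ValueError("snippet length does not match span")


def annotate(kind: str, sequence: str, start: int, end: int, score: float,
             register: int | None = None) -> DomainAnnotation:
    return DomainAnnotation(kind, start, end, score, sequence[start - 1:end], register)


@dataclass
class HsfArchitecture:
    """Measured Hsf architecture: DBD, HR-A/B and the derived lengths.

    ``linker_len`` counts residues strictly between DBD end and HR-A/B
    start; ``insertion_len`` counts residues strictly between the HR-A and
    HR-B sub-blocks (about 21 in class A, 7 in class C, none in class B).
    """

    dbd: DomainAnnotation
    hrab: DomainAnnotation
    linker_len: int
    insertion_len: int
    hr_a: DomainAnnotation | None = None
    hr_b: DomainAnnotation | None = None
    signals: list[DomainAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dbd.end >= self.hrab.start:
            raise ValueError("DBD must precede the HR-A/B region")
        if self.linker_len < 0 or self.insertion_len < 0:
            raise ValueError("negative linker or insertion length")


class IncompleteArchitecture(ValueError):
    """Raised when no coiled-coil region follows the DBD."""


# ---------------------------------------------------------------------------
# DBD profile scan


def dbd_profile_scores(sequence: str, consensus: str | None = None,
                       match_prob: float | None = None,
                       background: float | None = None) -> np.ndarray:
    """Log-odds profile score of every window of the packaged DBD profile."""
    consensus = consensus or _DBD["consensus"]
    match_prob = match_prob if match_prob is not None else _DBD["match_prob"]
    background = background if background is not None else _DBD["background_prob"]
    L, W = len(sequence), len(consensus)
    if L < W:
        return np.empty(0)
    s_match = np.log(match_prob / background)
    s_miss = np.log((1.0 - match_prob) / 19.0 / background)
    seq = _encode(sequence)
    cons = _encode(consensus)
    windows = np.lib.stride_tricks.sliding_window_view(seq, W)
    return np.where(windows == cons, s_match, s_miss).sum(axis=1)


def scan_dbd(p: ProteinRecord, threshold: float = 100.0) -> DomainAnnotation | None:
    """Best-window DBD hit above ``threshold`` log-odds, or None.

    A well-conserved instance of the packaged profile scores ~180-250;
    unrelated sequence scores far below zero.
    """
    scores = dbd_profile_scores(p.sequence)
    if scores.size == 0:
        return None
    i = int(np.argmax(scores))
    if scores[i] < threshold:
        return None
    W = len(_DBD["consensus"])
    return annotate("DBD", p.sequence, i + 1, i + W, float(scores[i]))


# ---------------------------------------------------------------------------
# Coiled-coil scan


def _window_register_scores(seq: np.ndarray, window: int) -> np.ndarray:
    """Mean log-propensity of each window under each heptad register.

    Returns array (n_windows, 7); register r places sequence position i at
    heptad slot (i + r) mod 7, slots 0 and 3 being the hydrophobic core.
    """
    L = seq.size
    n_win = L - window + 1
    if n_win <= 0:
        return np.empty((0, 7))
    pos = np.arange(L)
    out = np.empty((n_win, 7))
    ad_scores = _LOG_AD[seq]
    other_scores = _LOG_OTHER[seq]
    for r in range(7):
        slot = (pos + r) % 7
        per_res = np.where((slot == 0) | (slot == 3), ad_scores, other_scores)
        csum = np.concatenate(([0.0], np.cumsum(per_res)))
        out[:, r] = (csum[window:] - csum[:-window]) / window
    return out


def coil_residue_scores(sequence: str, window: int = 28) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue coiled-coil score: best score among windows covering the
    residue, with the winning register. Returns (scores, registers)."""
    seq = _encode(sequence)
    L = seq.size
    scores = np.full(L, -np.inf)
    registers = np.zeros(L, dtype=int)
    win_scores = _window_register_scores(seq, window)
    if win_scores.size == 0:
        return scores, registers
    best_reg = np.argmax(win_scores, axis=1)
    best = win_scores[np.arange(win_scores.shape[0]), best_reg]
    for w in range(best.size):
        sl = slice(w, w + window)
        better = best[w] > scores[sl]
        scores[sl] = np.where(better, best[w], scores[sl])
        registers[sl] = np.where(better, best_reg[w], registers[sl])
    return scores, registers


def scan_coiled_coil(
    p: ProteinRecord,
    window: int = 28,
    threshold: float = 0.2,
    merge_gap: int = 3,
    min_len: int = 14,
) -> list[DomainAnnotation]:
    """Detect coiled-coil segments as maximal runs of residues whose best
    window score exceeds ``threshold``, merged across gaps <= ``merge_gap``
    and filtered to runs of at least ``min_len`` residues."""
    if len(p) < window:
        return []
    scores, registers = coil_residue_scores(p.sequence, window)
    above = scores > threshold
    runs = _runs(above)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if e - s + 1 < min_len:
            continue
        seg_scores = scores[s:e + 1]
        peak = int(np.argmax(seg_scores))
        out.append(
            annotate("HRAB", p.sequence, s + 1, e + 1, float(seg_scores[peak]),
                     register=int(registers[s + peak]))
        )
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """0-based inclusive (start, end) runs of True."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1]) - 1) for i in range(0, idx.size, 2)]


# ---------------------------------------------------------------------------
# Architecture measurement


def measure_architecture(
    p: ProteinRecord,
    dbd: DomainAnnotation | None,
    coil_segments: Sequence[DomainAnnotation],
    max_insertion: int = 30,
    smooth: int = 7,
) -> HsfArchitecture:
    """Measure linker and HR-A/B insertion lengths from scanner output.

    The HR-A/B region is the first chain of coil segments after the DBD
    (segments separated by at most ``max_insertion`` residues belong to one
    region, allowing for the class-A insertion). Within the region the HR-A
    and HR-B sub-blocks are the two highest-scoring smoothed heptad runs
    under the region's best register; the insertion is the gap strictly
    between them. A single run means a compact, uninterrupted HR-A/B
    (insertion 0).
    """
    if dbd is None:
        raise IncompleteArchitecture("no DBD detected")
    # window bleed can pull a segment start back over the DBD end when the
    # linker is short; clip rather than discard such segments
    after = sorted(
        (
            seg if seg.start > dbd.end
            else annotate(seg.kind, p.sequence, dbd.end + 1, seg.end,
                          seg.score, seg.register)
            for seg in coil_segments
            if seg.end > dbd.end
        ),
        key=lambda seg: seg.start,
    )
    if not after:
        raise IncompleteArchitecture("no coiled-coil region after the DBD")
    chain = [after[0]]
    for seg in after[1:]:
        if seg.start - chain[-1].end - 1 <= max_insertion:
            chain.append(seg)
        else:
            break
    region_start, region_end = chain[0].start, chain[-1].end  # 1-based
    register = chain[0].register if chain[0].register is not None else 0

    runs = _refined_runs(p.sequence, region_start, region_end, register, smooth)
    if not runs:
        # fall back to the coarse segments
        runs = [(seg.start, seg.end, seg.score) for seg in chain]
    # rejoin fragments: boundary snapping can split or overlap runs; gaps of
    # <= 3 residues are within the compact (class-B) insertion threshold
    merged_runs: list[list] = []
    for s, e, sc in sorted(runs):
        if merged_runs and s - merged_runs[-1][1] - 1 <= 3:
            merged_runs[-1][1] = max(merged_runs[-1][1], e)
            merged_runs[-1][2] = max(merged_runs[-1][2], sc)
        else:
            merged_runs.append([s, e, sc])
    # an HR sub-block spans >= 2 heptads; shorter leftovers are polar noise
    kept = [tuple(r) for r in merged_runs if r[1] - r[0] + 1 >= 14]
    runs = kept or [tuple(r) for r in merged_runs]
    if len(runs) == 1:
        hr_a = annotate("HRA", p.sequence, runs[0][0], runs[0][1], runs[0][2], register)
        hr_b = None
        insertion = 0
        hrab = annotate("HRAB", p.sequence, runs[0][0], runs[0][1], runs[0][2], register)
    else:
        top = sorted(sorted(runs, key=lambda r: -r[2])[:2])
        hr_a = annotate("HRA", p.sequence, top[0][0], top[0][1], top[0][2], register)
        hr_b = annotate("HRB", p.sequence, top[1][0], top[1][1], top[1][2], register)
        insertion = hr_b.start - hr_a.end - 1
        hrab = annotate("HRAB", p.sequence, hr_a.start, hr_b.end,
                        max(hr_a.score, hr_b.score), register)
    linker = hrab.start - dbd.end - 1
    if linker < 0:
        raise IncompleteArchitecture("coiled-coil region overlaps the DBD")
    return HsfArchitecture(
        dbd=dbd, hrab=hrab, linker_len=linker, insertion_len=insertion,
        hr_a=hr_a, hr_b=hr_b,
    )


def _refined_runs(sequence: str, start: int, end: int, register: int,
                  smooth: int) -> list[tuple[int, int, float]]:
    """Smoothed per-residue heptad runs (1-based spans with mean score)
    inside [start, end] under a fixed register.

    Run starts are snapped forward to the first core ('a') slot holding a
    favorable residue, which pins the HR-A boundary (and hence the measured
    linker length) to the heptad frame rather than to smoothing bleed.
    """
    seq = _encode(sequence)
    pos = np.arange(seq.size)
    slot = (pos + register) % 7  # scan convention: position i at slot (i+r)%7
    core = (slot == 0) | (slot == 3)
    own = np.where(core, _LOG_AD[seq], _LOG_OTHER[seq])
    region = own[start - 1:end]
    if region.size == 0:
        return []
    kernel = np.ones(min(smooth, region.size)) / min(smooth, region.size)
    smoothed = np.convolve(region, kernel, mode="same")
    lo, hi = start - 1, end - 1
    runs = []
    for s, e in _runs(smoothed > 0):
        a0, a1 = start - 1 + s, start - 1 + e  # absolute 0-based
        # snap the start to the nearest favorable core ('a') slot, looking up
        # to one heptad back (smoothing can erode the first block residues)
        for p in range(max(lo, a0 - 6), a1 + 1):
            if slot[p] == 0 and _LOG_AD[seq[p]] > 0:
                a0 = p
                break
        # complete the final heptad: extend to just before the next 'a' slot
        while a1 + 1 <= hi and slot[a1 + 1] != 0:
            a1 += 1
        if a1 - a0 + 1 < 7:  # drop sub-heptad fragments
            continue
        score = float(smoothed[a0 - (start - 1):a1 - (start - 1) + 1].mean())
        runs.append((a0 + 1, a1 + 1, score))
    return runs


# ---------------------------------------------------------------------------
# Signal motifs

_AROMATIC = set("WFY")
_HYDROPHOBIC = set("LIV")
_NES_HYDROPHOBIC = set("LIVMF")
_ACIDIC = set("DE")
_BASIC = set("KR")


def find_signal_motifs(p: ProteinRecord) -> list[DomainAnnotation]:
    """Locate NLS, NES and AHA candidate motifs.

    NLS: >= 3 K/R within a 4-6 residue window, anywhere in the sequence.
    NES: leucine-rich window of 8-11 residues with >= 3 large hydrophobics
    (L/I/V/M/F) of which >= 2 are leucines, and AHA: an 8-10 residue window
    with >= 1 aromatic (W/F/Y), >= 1 large hydrophobic (L/I/V) and >= 2
    acidic (D/E) residues; NES and AHA are restricted to the C-terminal
    half where these export/activator elements reside. Overlapping windows
    of one kind are merged into maximal annotations.
    """
    seq = p.sequence
    half = len(seq) // 2
    out: list[DomainAnnotation] = []
    out += _window_motifs(seq, "NLS", sizes=(4, 5, 6), min_start=0,
                          test=lambda w: sum(c in _BASIC for c in w) >= 3,
                          trim=_BASIC)
    out += _window_motifs(
        seq, "AHA", sizes=(8, 9, 10), min_start=half,
        test=lambda w: (
            sum(c in _AROMATIC for c in w) >= 1
            and sum(c in _HYDROPHOBIC for c in w) >= 1
            and sum(c in _ACIDIC for c in w) >= 2
        ),
    )
    out += _window_motifs(
        seq, "NES", sizes=(8, 9, 10, 11), min_start=half,
        test=lambda w: (
            sum(c in _NES_HYDROPHOBIC for c in w) >= 3 and w.count("L") >= 2
        ),
        trim=_NES_HYDROPHOBIC,
    )
    return sorted(out, key=lambda a: (a.start, a.kind))


def _window_motifs(seq: str, kind: str, sizes: tuple[int, ...], min_start: int,
                   test, trim: set | None = None) -> list[DomainAnnotation]:
    hit = np.zeros(len(seq), dtype=bool)
    smallest = min(sizes)
    for i in range(min_start, len(seq) - smallest + 1):
        for size in sizes:
            w = seq[i:i + size]
            if len(w) < size:
                continue
            if test(w):
                lo, hi = i, i + size - 1
                if trim is not None:  # shrink to the motif-content boundaries
                    while lo < hi and seq[lo] not in trim:
                        lo += 1
                    while hi > lo and seq[hi] not in trim:
                        hi -= 1
                hit[lo:hi + 1] = True
                break  # smallest qualifying window at this start
    return [
        annotate(kind, seq, s + 1, e + 1, 0.0) for s, e in _runs(hit)
    ]
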