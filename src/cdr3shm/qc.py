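"""Read QC: length/quality filters, paired-end merging, CDR3-window filter.

The QC stages mirror an amplicon AIRR-seq pipeline: (1) per-mate length and
mean-quality filters, (2) overlap merging of the pair with per-base
quality-aware consensus, (3) length/quality filtering of the merged read,
and (4) a CDR3-safety filter requiring Phred >= 30 for every base in the
30-45 nt stretch ahead of the FR4 G-X-G anchor — the window where the 3'
portion of a 13-21 aa CDR3 lies, so the positions this analysis calls
substitutions in are guaranteed high-quality.

Every operation exists in a scalar form (exact, used on fixtures and small
inputs) and a batched numpy form used by the pipeline on equal-length read
matrices; the batched forms are tested against the scalar ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seqtools import encode, pair_offset_scan, revcomp_arr, translate_arr

W, G = ord("W"), ord("G")


@dataclass
class MergedRead:
    """A merged read pair: sequence with per-base Phred scores."""

    sequence: str
    qualities: np.ndarray
    sample_id: str = ""
    isotype: str = ""

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")
        if self.qualities.min(initial=0) < 0 or self.qualities.max(initial=0) > 60:
            raise ValueError("qualities must lie in [0, 60]")


@dataclass
class QCReport:
    """Per-sample tally of filter outcomes; every read lands in exactly one
    outcome per stage."""

    counts: dict = field(default_factory=dict)

    def add(self, outcome: str, n: int = 1) -> None:
        self.counts[outcome] = self.counts.get(outcome, 0) + n


def merge_pair(
    r1_seq: str,
    r1_qual,
    r2_seq: str,
    r2_qual,
    min_overlap: int = 30,
    max_mismatch_frac: float = 0.25,
) -> MergedRead | None:
    """Merge one read pair by exhaustive overlap scan; None = rejection.

    r2 is reverse-strand and is reverse-complemented first.  Among all
    offsets with overlap >= ``min_overlap`` and mismatch fraction <=
    ``max_mismatch_frac`` the placement with fewest mismatches wins (ties:
    larger overlap, then smaller offset).  Disagreeing overlap bases resolve
    to the higher-quality call (tie: r1) and merged quality is the max of
    the two.
    """
    a = encode(r1_seq)
    qa = np.asarray(r1_qual, dtype=np.int16)
    b = revcomp_arr(encode(r2_seq))
    qb = np.asarray(r2_qual, dtype=np.int16)[::-1]
    L1, L2 = len(a), len(b)

    best = None  # (mismatches, -overlap, offset)
    for s in range(min_overlap - L2, L1 - min_overlap + 1):
        a0, a1 = max(0, s), min(L1, s + L2)
        ov = a1 - a0
        if ov < min_overlap:
            continue
        mm = int(np.count_nonzero(a[a0:a1] != b[a0 - s: a1 - s]))
        if mm / ov > max_mismatch_frac:
            continue
        key = (mm, -ov, s)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    _, _, s = best
    return _consensus(a, qa, b, qb, s)


def _consensus(a, qa, b, qb, s: int) -> MergedRead:
    L1, L2 = len(a), len(b)
    lo, hi = min(0, s), max(L1, s + L2)
    seq = np.zeros(hi - lo, dtype=np.uint8)
    qual = np.zeros(hi - lo, dtype=np.int16)
    # a occupies [0,L1), b occupies [s, s+L2) in merged coords shifted by -lo
    seq[-lo: L1 - lo] = a
    qual[-lo: L1 - lo] = qa
    b_sl = slice(s - lo, s - lo + L2)
    only_b = np.ones(hi - lo, dtype=bool)
    only_b[-lo: L1 - lo] = False
    both = np.zeros(hi - lo, dtype=bool)
    both[b_sl] = True
    onlyb_in_b = only_b[b_sl]
    seq[b_sl] = np.where(onlyb_in_b, b, seq[b_sl])
    qual[b_sl] = np.where(onlyb_in_b, qb, qual[b_sl])
    both &= ~only_b
    both[: s - lo] = False
    both[s - lo + L2:] = False
    # overlap: take b where strictly higher quality
    ov_idx = np.flatnonzero(both)
    bq = qb[ov_idx - (s - lo)]
    ba = b[ov_idx - (s - lo)]
    takeb = bq > qual[ov_idx]
    seq[ov_idx[takeb]] = ba[takeb]
    qual[ov_idx] = np.maximum(qual[ov_idx], bq)
    return MergedRead(seq.tobytes().decode("ascii"), qual)


@dataclass
class MergedBatch:
    """Batched merge output: one entry per distinct merged length."""

    seqs: np.ndarray  # (m, L) uint8
    quals: np.ndarray  # (m, L) int16
    src_index: np.ndarray  # row index into the input pair arrays


def merge_batch(
    r1: np.ndarray,
    q1: np.ndarray,
    r2: np.ndarray,
    q2: np.ndarray,
    min_overlap: int = 30,
    max_mismatch_frac: float = 0.25,
    nonnegative: bool = True,
) -> tuple[list[MergedBatch], int]:
    """Merge equal-length read-pair matrices; returns (groups, n_rejected).

    ``nonnegative`` restricts the offset scan to placements where the
    reverse mate does not overhang the forward mate's 5' end — always the
    case for amplicons at least one read length long.
    """
    b = revcomp_arr(r2)
    qb = np.asarray(q2, dtype=np.int16)[:, ::-1]
    qa = np.asarray(q1, dtype=np.int16)
    off, mm, ov = pair_offset_scan(
        r1, b, min_overlap, nonnegative=nonnegative,
        max_mismatch_frac=max_mismatch_frac,
    )
    ok = mm >= 0
    groups = []
    for s in np.unique(off[ok]):
        idx = np.flatnonzero(ok & (off == s))
        L1, L2 = r1.shape[1], b.shape[1]
        s = int(s)
        lo, hi = min(0, s), max(L1, s + L2)
        m = len(idx)
        seq = np.zeros((m, hi - lo), dtype=np.uint8)
        qual = np.zeros((m, hi - lo), dtype=np.int16)
        seq[:, -lo: L1 - lo] = r1[idx]
        qual[:, -lo: L1 - lo] = qa[idx]
        bcols = np.arange(s - lo, s - lo + L2)
        in_a = (bcols >= -lo) & (bcols < L1 - lo)
        # positions covered only by b
        seq[:, bcols[~in_a]] = b[idx][:, ~in_a]
        qual[:, bcols[~in_a]] = qb[idx][:, ~in_a]
        # overlap columns: higher quality wins, tie -> r1
        oc = bcols[in_a]
        takeb = qb[idx][:, in_a] > qual[:, oc]
        sub = seq[:, oc]
        sub[takeb] = b[idx][:, in_a][takeb]
        seq[:, oc] = sub
        qual[:, oc] = np.maximum(qual[:, oc], qb[idx][:, in_a])
        groups.append(MergedBatch(seq, qual, idx))
    return groups, int(np.count_nonzero(~ok))


def basic_filters(
    seq_len: int,
    mean_q: float,
    min_len: int = 200,
    max_len: int = 350,
    min_mean_q: float = 25.0,
) -> tuple[bool, str]:
    """Length and mean-quality filter; bounds are inclusive.

    Returns (passed, reason) with reason one of pass/too_short/too_long/
    low_mean_q.
    """
    if seq_len < min_len:
        return False, "too_short"
    if seq_len > max_len:
        return False, "too_long"
    if mean_q < min_mean_q:
        return False, "low_mean_q"
    return True, "pass"


def find_gxg_anchor(seq: str, frame: int | None = None) -> int | None:
    """Nucleotide offset of the FR4 G-X-G motif start (first base of the G
    codon following the conserved J tryptophan), or None.

    The anchor is the aa motif W-G-x-G; with ``frame=None`` all three frames
    are scanned and the rightmost hit wins (FR4 is J-encoded and
    3'-terminal).
    """
    arr = encode(seq)
    frames = (frame,) if frame is not None else (0, 1, 2)
    best = None
    for f in frames:
        aa = translate_arr(arr[f:])
        n = len(aa)
        for i in range(n - 4, -1, -1):
            if aa[i] == W and aa[i + 1] == G and aa[i + 3] == G:
                pos = f + 3 * (i + 1)
                if best is None or pos > best:
                    best = pos
                break
    return best


def cdr3_window_filter(
    read: MergedRead,
    window_near: int = 30,
    window_far: int = 45,
    min_q: int = 30,
    frame: int | None = None,
) -> tuple[bool, str]:
    """Require Phred >= ``min_q`` at every base in the closed offset interval
    [-window_far, -window_near] ahead of the FR4 G-X-G anchor.

    Offsets are relative to the first base of the motif's first G codon;
    window positions falling outside the read are ignored.  A read without
    the anchor fails with reason ``no_anchor``.
    """
    anchor = find_gxg_anchor(read.sequence, frame=frame)
    if anchor is None:
        return False, "no_anchor"
    pos = anchor - np.arange(window_near, window_far + 1)
    pos = pos[(pos >= 0) & (pos < len(read.sequence))]
    if np.all(read.qualities[pos] >= min_q):
        return True, "pass"
    return False, "low_q_cdr3_window"


def gxg_anchor_batch(seqs: np.ndarray) -> np.ndarray:
    """Rightmost W-G-x-G anchor (nt offset) per row; -1 where absent."""
    n, L = seqs.shape
    best = np.full(n, -1, dtype=np.int64)
    for f in (0, 1, 2):
        aa = translate_arr(seqs[:, f:])
        if aa.shape[1] < 4:
            continue
        hit = (aa[:, :-3] == W) & (aa[:, 1:-2] == G) & (aa[:, 3:] == G)
        any_hit = hit.any(axis=1)
        # rightmost aa index per row
        last = hit.shape[1] - 1 - np.argmax(hit[:, ::-1], axis=1)
        pos = f + 3 * (last + 1)
        best = np.where(any_hit & (pos > best), pos, best)
    return best


def cdr3_window_filter_batch(
    seqs: np.ndarray,
    quals: np.ndarray,
    window_near: int = 30,
    window_far: int = 45,
    min_q: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised window filter; returns (pass mask, anchor positions)."""
    n, L = seqs.shape
    anchor = gxg_anchor_batch(seqs)
    offs = np.arange(window_near, window_far + 1)
    pos = anchor[:, None] - offs[None, :]
    valid = (pos >= 0) & (pos < L)
    q = np.where(valid, quals[np.arange(n)[:, None], np.clip(pos, 0, L - 1)], min_q)
    ok = (anchor >= 0) & np.all(q >= min_q, axis=1)
    return ok, anchor
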