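"""Low-level nucleotide utilities shared across the package.

Sequences travel in two forms: python ``str`` for the scalar APIs and
``numpy.uint8`` arrays of ASCII codes for the batched pipeline path.  The
batched helpers assume substitution-only data (equal-length rows), which is
the regime this pipeline operates in: the read simulator introduces no
indels and the pipeline's length filters discard aberrant-length variants
anyway.
"""
from __future__ import annotations

import numpy as np

A, C, G, T = 65, 67, 71, 84
_ACGT = frozenset("ACGT")

# 256-entry complement table (identity outside ACGT; upstream validation
# rejects anything else before it reaches the hot path).
_COMP = np.arange(256, dtype=np.uint8)
for x, y in ((A, T), (C, G), (G, C), (T, A)):
    _COMP[x] = y

# Codon translation: base -> 0..3 index in TCAG order; codon = 16a+4b+c.
_BASE_IDX = np.full(256, -1, dtype=np.int16)
for i, b in enumerate("TCAG"):
    _BASE_IDX[ord(b)] = i
_AA64 = np.frombuffer(
    b"FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    dtype=np.uint8,
).copy()

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_acgt(seq: str) -> bool:
    return bool(seq) and set(seq) <= _ACGT


def encode(seq: str) -> np.ndarray:
    """ASCII-encode a nucleotide string as uint8."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return np.ascontiguousarray(arr).tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return decode(_COMP[encode(seq)][::-1])


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    """Reverse-complement along the last axis."""
    return _COMP[arr][..., ::-1]


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string (standard code, '*' = stop)."""
    return translate_arr(encode(seq)).tobytes().decode("ascii")


def translate_arr(arr: np.ndarray) -> np.ndarray:
    """Translate uint8 ASCII nucleotides; works on (..., L) arrays.

    Trailing bases beyond the last full codon are ignored.
    """
    n = arr.shape[-1] - arr.shape[-1] % 3
    idx = _BASE_IDX[arr[..., :n]]
    if np.any(idx < 0):
        raise ValueError("non-ACGT character in sequence")
    codons = 16 * idx[..., 0::3] + 4 * idx[..., 1::3] + idx[..., 2::3]
    return _AA64[codons]


def unique_rows(mat: np.ndarray, weights: np.ndarray | None = None):
    """Deduplicate matrix rows; returns (unique_matrix, summed_weights).

    Dict-of-bytes grouping (ordered by first occurrence, then re-sorted
    lexicographically for determinism); far faster than sorting wide rows.
    """
    n = mat.shape[0]
    if weights is None:
        weights = np.ones(n, dtype=np.int64)
    acc: dict[bytes, int] = {}
    for i in range(n):
        b = mat[i].tobytes()
        acc[b] = acc.get(b, 0) + int(weights[i])
    keys = sorted(acc)
    uniq = np.frombuffer(b"".join(keys), dtype=mat.dtype).reshape(len(keys), -1)
    counts = np.array([acc[k] for k in keys], dtype=np.int64)
    return uniq.copy(), counts


def _resolve(
    mm_list: list[np.ndarray],
    ov: np.ndarray,
    offsets: np.ndarray,
    span: int,
    max_mismatch_frac: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pick, per read, min mismatches; ties -> larger overlap -> smaller offset.

    With ``max_mismatch_frac`` only offsets satisfying the cap compete; reads
    with no admissible offset get mismatches = -1.
    """
    mm = np.stack(mm_list)  # (n_off, n_reads)
    score = mm.astype(np.int64) * (span + 1) - ov[:, None]
    if max_mismatch_frac is not None:
        bad = mm > max_mismatch_frac * ov[:, None]
        score = np.where(bad, np.iinfo(np.int64).max, score)
    pick = np.argmin(score, axis=0)  # first minimum = smallest offset on ties
    rows = np.arange(mm.shape[1])
    best_mm = mm[pick, rows].astype(np.int64)
    if max_mismatch_frac is not None:
        none_ok = score[pick, rows] == np.iinfo(np.int64).max
        best_mm[none_ok] = -1
    return offsets[pick], best_mm, ov[pick]


def pair_offset_scan(
    a: np.ndarray,
    b: np.ndarray,
    min_overlap: int,
    nonnegative: bool = False,
    max_mismatch_frac: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best relative placement of each row of ``b`` against the same row of ``a``.

    ``a`` is (n, L1), ``b`` is (n, L2); offset s means b starts at column s of
    a's coordinate system (negative = b overhangs to the left).  Returns per
    read the offset minimising overlap mismatches (ties: larger overlap, then
    smaller offset) among offsets with overlap >= min_overlap.

    With ``nonnegative`` only s >= 0 is scanned — appropriate for amplicon
    read pairs whose insert is at least one read length long.
    """
    n, L1 = a.shape
    L2 = b.shape[1]
    lo = 0 if nonnegative else min_overlap - L2
    hi = L1 - min_overlap
    offsets = np.arange(lo, hi + 1, dtype=np.int64)
    mm_list, ov = [], np.empty(len(offsets), dtype=np.int64)
    for k, s in enumerate(offsets):
        a0, a1 = max(0, s), min(L1, s + L2)
        ov[k] = a1 - a0
        mm_list.append(
            np.count_nonzero(a[:, a0:a1] != b[:, a0 - s: a1 - s], axis=1).astype(np.int32)
        )
    return _resolve(mm_list, ov, offsets, L1 + L2, max_mismatch_frac)


def ref_offset_scan(
    reads: np.ndarray,
    ref: np.ndarray,
    offsets: np.ndarray | None = None,
    full_cover: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slide a single reference along equal-length reads; per-read best offset.

    By default only placements with the reference fully inside the read are
    scanned (``full_cover``); reads shorter than the reference get partial
    placements instead.
    """
    n, L = reads.shape
    m = len(ref)
    if offsets is None:
        if full_cover and L >= m:
            offsets = np.arange(0, L - m + 1, dtype=np.int64)
        else:
            offsets = np.arange(-(m - 1), L, dtype=np.int64)
    mm_list, ov = [], np.empty(len(offsets), dtype=np.int64)
    for k, s in enumerate(offsets):
        a0, a1 = max(0, s), min(L, s + m)
        if a1 <= a0:
            ov[k] = 0
            mm_list.append(np.full(n, np.iinfo(np.int32).max // 2, dtype=np.int32))
            continue
        ov[k] = a1 - a0
        seg = ref[a0 - s: a1 - s]
        mm_list.append(np.count_nonzero(reads[:, a0:a1] != seg, axis=1).astype(np.int32))
    return _resolve(mm_list, ov, np.asarray(offsets, dtype=np.int64), L + m)
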