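"""Simplified V(D)J annotation: segment assignment, germline identity, CDR3.

A gap-free semi-global aligner stands in for a full repertoire annotator:
the analysis concerns substitutions only, and aberrant-length variants are
discarded downstream by the same-CDR3-length rule, so gapped alignment is
unnecessary.  Scoring is +1 match / -2 mismatch with ties broken by
lexicographic segment name.  D genes are assigned by longest exact
substring match (>= 5 nt) between the junction and any D segment, the
classic short-segment heuristic.

V-gene germline identity is computed over FR1-FR3 only: mutations 3' of the
FR3 boundary (i.e. in the CDR3) never reduce it, which is what makes the
"truly unmutated, 100% identity" filter meaningful while the CDR3 varies.

Scalar entry point: :func:`annotate_read`.  The pipeline uses
:func:`annotate_batch` on equal-length uint8 matrices; both paths share the
same conventions and the batch path is tested against the scalar one.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seqtools import decode, encode, ref_offset_scan, translate, translate_arr
from .germline import CDR3_REGIONS, GeneSegment, GermlineDB

_REGION_ORDER = {r: i for i, r in enumerate(CDR3_REGIONS)}


@dataclass
class SegmentAlignment:
    """Gap-free placement of a germline segment on a read."""

    segment: GeneSegment
    offset: int  # read position of segment base 0 (may be negative if clipped)
    mismatches: int
    overlap: int

    @property
    def score(self) -> int:
        return self.overlap - 3 * self.mismatches

    @property
    def end(self) -> int:
        return self.offset + len(self.segment.sequence)

    def region_mismatches(self, seq: str) -> dict[str, int]:
        """Mismatch count per named V region (FR1..FR3 + CDRs) of the
        aligned segment; junction-tail mismatches land under 'junction'."""
        a = encode(seq)
        ref = encode(self.segment.sequence)
        out: dict[str, int] = {}
        bounds = dict(self.segment.region_bounds)
        if self.segment.segment_class == "V":
            bounds["junction"] = [self.segment.fr3_end, len(ref)]
        for name, (lo, hi) in bounds.items():
            lo_r = self.offset + lo
            hi_r = self.offset + hi
            if lo_r < 0 or hi_r > len(a):
                continue
            out[name] = int(np.count_nonzero(a[lo_r:hi_r] != ref[lo:hi]))
        return out


@dataclass
class DAssignment:
    segment: GeneSegment
    junction_start: int  # within the searched junction window
    length: int
    d_start: int  # within the D segment
    reading_frame: int


@dataclass
class AnnotatedRearrangement:
    """One read's annotation: calls, FR1-FR3 identity, CDR3 with provenance."""

    sequence: str
    v_call: str | None
    d_call: str | None
    j_call: str | None
    v_identity: float | None  # percent over FR1-FR3
    junction_nt: str | None  # C104 codon .. W118 codon inclusive
    cdr3_nt: str | None
    cdr3_aa: str | None
    cdr3_start: int | None
    region_of_cdr3_codon: dict | None  # 1-based position -> V/N1/D/N2/J
    germline_cdr3_ref: str | None  # germline bases at templated positions
    productive: bool
    isotype: str = ""
    sample_id: str = ""


def _best_alignment(
    seq_arr: np.ndarray, segments: list[GeneSegment], min_offset: int = 0
) -> SegmentAlignment | None:
    """Highest-scoring gap-free placement across segments (full coverage of
    the segment when the read is long enough)."""
    best = None
    L = len(seq_arr)
    for seg in sorted(segments, key=lambda s: s.name):
        ref = encode(seg.sequence)
        m = len(ref)
        hi = L - m
        if hi < min_offset:
            continue
        offsets = np.arange(min_offset, hi + 1)
        off, mm, ov = ref_offset_scan(seq_arr[None, :], ref, offsets=offsets)
        cand = SegmentAlignment(seg, int(off[0]), int(mm[0]), int(ov[0]))
        if best is None or cand.score > best.score:
            best = cand
    return best


def align_v(
    seq: str, v_segments: list[GeneSegment], score_floor: float = 0.0
) -> SegmentAlignment | None:
    """Best V placement, or None (unassigned) when below the score floor.

    The default floor of 0 corresponds to ~67% identity over the segment;
    random sequence scores far below it.
    """
    if len(seq) < 100:
        raise ValueError("sequence shorter than 100 nt cannot be V-annotated")
    best = _best_alignment(encode(seq), v_segments)
    if best is None or best.score < score_floor:
        return None
    return best


def align_j(
    seq: str,
    j_segments: list[GeneSegment],
    search_from: int = 0,
    score_floor: float = 0.0,
) -> SegmentAlignment | None:
    """Best J placement 3' of ``search_from`` (typically the V match end)."""
    best = _best_alignment(encode(seq), j_segments, min_offset=search_from)
    if best is None or best.score < score_floor:
        return None
    return best


def assign_d(
    junction_nt: str,
    d_segments: list[GeneSegment],
    min_match: int = 5,
    codon_phase: int = 0,
) -> DAssignment | None:
    """Longest exact substring match between the junction window and any D.

    Ties: longest, then 5'-most in the junction, then segment name.
    ``codon_phase`` is the codon offset (0-2) of ``junction_nt[0]`` within
    the rearrangement's reading frame and yields the D reading frame (frame
    f = translation starting at D nucleotide f-1).  Absence of a match is a
    legal outcome (None).
    """
    best = None  # (-length, junction_start, name)
    for seg in sorted(d_segments, key=lambda s: s.name):
        d = seg.sequence
        n, m = len(junction_nt), len(d)
        for i in range(n):
            if best is not None and n - i < -best[0][0]:
                break
            # longest match starting at junction position i
            length, d_at = 0, -1
            for j in range(m):
                k = 0
                while i + k < n and j + k < m and junction_nt[i + k] == d[j + k]:
                    k += 1
                if k > length:
                    length, d_at = k, j
            if length >= min_match:
                key = (-length, i, seg.name)
                if best is None or key < best[0]:
                    frame = 1 + (d_at + (3 - (codon_phase + i) % 3)) % 3
                    best = (key, DAssignment(seg, i, length, d_at, frame))
    return None if best is None else best[1]


def compute_v_identity(seq: str, v_aln: SegmentAlignment) -> float | None:
    """Percent identity over FR1-FR3 positions only; None if the alignment
    does not reach the FR3 end (read flagged incomplete, excluded)."""
    fr3_end = v_aln.segment.fr3_end
    start = v_aln.offset
    if start < 0 or start + fr3_end > len(seq):
        return None
    a = encode(seq)[start: start + fr3_end]
    b = encode(v_aln.segment.sequence)[:fr3_end]
    return 100.0 * float(np.count_nonzero(a == b)) / fr3_end


def _codon_regions(nt_labels: list[str]) -> dict[int, str]:
    out = {}
    for p in range(len(nt_labels) // 3):
        triplet = nt_labels[3 * p: 3 * p + 3]
        out[p + 1] = max(
            set(triplet), key=lambda r: (triplet.count(r), -_REGION_ORDER[r])
        )
    return out


def extract_cdr3(
    seq: str,
    v_aln: SegmentAlignment,
    j_aln: SegmentAlignment,
    d_assignment: DAssignment | None,
) -> dict:
    """Delimit the CDR3 (post-C104 codon to pre-W codon) and label codons.

    Returns a dict with cdr3_nt/cdr3_aa/junction_nt/region map/productive
    flag and the germline CDR3 reference (germline bases at templated
    positions, the read's own bases at N positions).  A frame-shifted
    junction yields productive=False with CDR3 fields None.
    """
    cdr3_start = v_aln.offset + v_aln.segment.fr3_end
    cdr3_end = j_aln.offset + j_aln.segment.fr4_start
    length = cdr3_end - cdr3_start
    if length <= 0 or length % 3:
        return {
            "cdr3_start": cdr3_start, "cdr3_nt": None, "cdr3_aa": None,
            "junction_nt": None, "regions": None, "germline_ref": None,
            "productive": False,
        }
    cdr3_nt = seq[cdr3_start:cdr3_end]
    cdr3_aa = translate(cdr3_nt)
    # junction-level productivity: in frame (checked above), stop-free CDR3.
    # Callers additionally require a stop-free full-length translation.
    productive = "*" not in cdr3_aa

    v_end = v_aln.end
    d_abs_start = d_abs_end = None
    if d_assignment is not None:
        d_abs_start = v_end + d_assignment.junction_start
        d_abs_end = d_abs_start + d_assignment.length
    labels, ref = [], []
    for pos in range(cdr3_start, cdr3_end):
        if pos < v_end:
            labels.append("V")
            ref.append(v_aln.segment.sequence[pos - v_aln.offset])
        elif d_abs_start is not None and d_abs_start <= pos < d_abs_end:
            labels.append("D")
            ref.append(
                d_assignment.segment.sequence[
                    d_assignment.d_start + (pos - d_abs_start)
                ]
            )
        elif pos >= j_aln.offset:
            labels.append("J")
            ref.append(j_aln.segment.sequence[pos - j_aln.offset])
        elif d_abs_start is None or pos < d_abs_start:
            labels.append("N1")
            ref.append(seq[pos])
        else:
            labels.append("N2")
            ref.append(seq[pos])
    return {
        "cdr3_start": cdr3_start,
        "cdr3_nt": cdr3_nt,
        "cdr3_aa": cdr3_aa,
        "junction_nt": seq[cdr3_start - 3: cdr3_end + 3],
        "regions": _codon_regions(labels),
        "germline_ref": "".join(ref),
        "productive": productive,
    }


def annotate_read(
    seq: str,
    db: GermlineDB,
    isotype: str = "",
    sample_id: str = "",
    min_d_match: int = 5,
) -> AnnotatedRearrangement:
    """Full scalar annotation of one read."""
    empty = dict(
        sequence=seq, v_call=None, d_call=None, j_call=None, v_identity=None,
        junction_nt=None, cdr3_nt=None, cdr3_aa=None, cdr3_start=None,
        region_of_cdr3_codon=None, germline_cdr3_ref=None, productive=False,
        isotype=isotype, sample_id=sample_id,
    )
    v_aln = align_v(seq, db.by_class("V"))
    if v_aln is None:
        return AnnotatedRearrangement(**empty)
    j_aln = align_j(seq, db.by_class("J"), search_from=v_aln.end)
    if j_aln is None:
        return AnnotatedRearrangement(**{**empty, "v_call": v_aln.segment.name})
    identity = compute_v_identity(seq, v_aln)
    junction_window = seq[v_aln.end: j_aln.offset]
    cdr3_start = v_aln.offset + v_aln.segment.fr3_end
    phase = (v_aln.end - cdr3_start) % 3
    d_asn = assign_d(
        junction_window, db.by_class("D"), min_match=min_d_match, codon_phase=phase
    )
    x = extract_cdr3(seq, v_aln, j_aln, d_asn)
    return AnnotatedRearrangement(
        sequence=seq,
        v_call=v_aln.segment.name,
        d_call=None if d_asn is None else d_asn.segment.name,
        j_call=j_aln.segment.name,
        v_identity=identity,
        junction_nt=x["junction_nt"],
        cdr3_nt=x["cdr3_nt"],
        cdr3_aa=x["cdr3_aa"],
        cdr3_start=x["cdr3_start"],
        region_of_cdr3_codon=x["regions"],
        germline_cdr3_ref=x["germline_ref"],
        productive=(
            x["productive"]
            and identity is not None
            and "*" not in translate(seq[v_aln.offset:])
        ),
        isotype=isotype,
        sample_id=sample_id,
    )


AIRR_COLUMNS = [
    "sequence_id", "sequence", "v_call", "d_call", "j_call", "junction",
    "junction_aa", "productive", "v_identity", "cdr3_region_map",
    "sample_id", "isotype", "duplicate_count",
]


def annotate_batch(
    seqs: np.ndarray,
    db: GermlineDB,
    counts: np.ndarray | None = None,
    isotype: str = "",
    sample_id: str = "",
    min_d_match: int = 5,
) -> pd.DataFrame:
    """Vectorised annotation of an equal-length uint8 sequence matrix.

    V and J placement is batched; junction-level work (D assignment, CDR3
    extraction) is memoised per unique (placement, junction) signature,
    which on repertoire data collapses to a handful of evaluations.  Output
    is an AIRR-style rearrangement table, one row per input row.
    """
    n, L = seqs.shape
    if counts is None:
        counts = np.ones(n, dtype=np.int64)

    # --- batched V placement
    v_segs = sorted(db.by_class("V"), key=lambda s: s.name)
    v_best_score = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
    v_idx = np.full(n, -1)
    v_off = np.zeros(n, dtype=np.int64)
    v_mm = np.zeros(n, dtype=np.int64)
    for k, seg in enumerate(v_segs):
        ref = encode(seg.sequence)
        if len(ref) > L:
            continue
        off, mm, ov = ref_offset_scan(seqs, ref)
        score = ov - 3 * mm
        better = score > v_best_score
        v_best_score[better] = score[better]
        v_idx[better], v_off[better], v_mm[better] = k, off[better], mm[better]
    v_ok = (v_idx >= 0) & (v_best_score >= 0)

    # --- batched J placement (3' of the V end, enforced after the scan)
    j_segs = sorted(db.by_class("J"), key=lambda s: s.name)
    j_best_score = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
    j_idx = np.full(n, -1)
    j_off = np.zeros(n, dtype=np.int64)
    for k, seg in enumerate(j_segs):
        ref = encode(seg.sequence)
        if len(ref) > L:
            continue
        off, mm, ov = ref_offset_scan(seqs, ref)
        score = ov - 3 * mm
        better = score > j_best_score
        j_best_score[better] = score[better]
        j_idx[better], j_off[better] = k, off[better]
    v_end = np.where(
        v_idx >= 0,
        v_off + np.array([len(s.sequence) for s in v_segs] or [0])[np.maximum(v_idx, 0)],
        0,
    )
    j_ok = (j_idx >= 0) & (j_best_score >= 0) & (j_off >= v_end)

    # --- per-read identity over FR1..FR3 for the chosen V
    identity = np.full(n, np.nan)
    for k, seg in enumerate(v_segs):
        ref = encode(seg.sequence)[: seg.fr3_end]
        for off in np.unique(v_off[(v_idx == k) & v_ok]):
            rows = np.flatnonzero((v_idx == k) & v_ok & (v_off == off))
            if off < 0 or off + len(ref) > L:
                continue
            mm = np.count_nonzero(seqs[rows, off: off + len(ref)] != ref, axis=1)
            identity[rows] = 100.0 * (len(ref) - mm) / len(ref)

    # --- full-read stop scan (in the V frame) per placement group
    no_stop = np.zeros(n, dtype=bool)
    stop = ord("*")
    for off in np.unique(v_off[v_ok]):
        rows_i = np.flatnonzero(v_ok & (v_off == off))
        aa = translate_arr(seqs[rows_i, off:])
        no_stop[rows_i] = ~(aa == stop).any(axis=1)

    # --- junction-level annotation, memoised
    rows = []
    cache: dict = {}
    for i in range(n):
        if not (v_ok[i] and j_ok[i]):
            rows.append(
                (None, None, None, np.nan, None, None, None, None, np.nan, False)
            )
            continue
        vseg, jseg = v_segs[v_idx[i]], j_segs[j_idx[i]]
        cdr3_start = int(v_off[i]) + vseg.fr3_end
        cdr3_end = int(j_off[i]) + jseg.fr4_start
        key = (vseg.name, int(v_off[i]), jseg.name, int(j_off[i]),
               decode(seqs[i, max(cdr3_start - 3, 0): min(cdr3_end + 3, L)]))
        if key not in cache:
            seq = decode(seqs[i])
            v_aln = SegmentAlignment(vseg, int(v_off[i]), int(v_mm[i]), len(vseg.sequence))
            j_aln = SegmentAlignment(jseg, int(j_off[i]), 0, len(jseg.sequence))
            phase = (v_aln.end - cdr3_start) % 3
            d_asn = assign_d(
                seq[v_aln.end: j_aln.offset], db.by_class("D"),
                min_match=min_d_match, codon_phase=phase,
            )
            x = extract_cdr3(seq, v_aln, j_aln, d_asn)
            cache[key] = (
                vseg.name,
                None if d_asn is None else d_asn.segment.name,
                jseg.name,
                x,
            )
        vname, dname, jname, x = cache[key]
        productive = bool(
            x["productive"] and not np.isnan(identity[i]) and no_stop[i]
        )
        rows.append(
            (vname, dname, jname, identity[i], x["junction_nt"], x["cdr3_aa"],
             x["regions"], x["germline_ref"], x["cdr3_start"], productive)
        )

    df = pd.DataFrame(
        rows,
        columns=["v_call", "d_call", "j_call", "v_identity", "junction",
                 "cdr3_aa", "cdr3_region_map", "germline_cdr3_ref",
                 "cdr3_start", "productive"],
    )
    df.insert(0, "sequence", [decode(seqs[i]) for i in range(n)])
    df.insert(0, "sequence_id", [f"{sample_id}:{isotype}:{i}" for i in range(n)])
    df["sample_id"] = sample_id
    df["isotype"] = isotype
    df["duplicate_count"] = counts
    return df


def write_airr_tsv(df: pd.DataFrame, path) -> None:
    """Write an AIRR-style rearrangement TSV (region map serialised)."""
    out = df.copy()
    out["junction_aa"] = out["cdr3_aa"]
    out["cdr3_region_map"] = out["cdr3_region_map"].map(
        lambda m: "" if m is None else ",".join(m[p] for p in sorted(m))
    )
    out.reindex(columns=AIRR_COLUMNS).to_csv(path, sep="\t", index=False)
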