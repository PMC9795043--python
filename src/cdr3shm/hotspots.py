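"""AID-hotspot scanning and mutation-to-hotspot topology.

Activation-induced deaminase (AID) targets cytosines in WRC motifs
(IUPAC: W=A/T, R=A/G; the C is the deaminated base).  The same motif on
the reverse strand reads GYW on the sense strand (Y=C/T), with the G
marking the reverse-strand C.  WGCW 4-mers carry overlapping WRC+GYW
hotspots on both strands; AGCT is the palindromic WGCW instance (its own
reverse complement, so the overlapping motif is present identically on
both strands).

A mutation is classed ``canonical_AID`` when it hits a deaminated site
itself; ``adjacent_AT_noncanonical`` when it changes an A/T within a small
neighbourhood of a hotspot (the error-prone-repair signature around the
deaminated base); otherwise ``unassociated``.  Junction-created hotspots —
motifs spanning a region boundary that do not exist in the pure germline
concatenation — are detected separately.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from ._seqtools import is_acgt
from .shm import SubstitutionEvent

_W = set("AT")
_R = set("AG")
_Y = set("CT")


@dataclass(frozen=True)
class HotspotHit:
    """One motif occurrence; interval is 0-based half-open on the sequence.

    ``deaminated_site`` is the C of a sense-strand WRC (or of the WGCW
    core), or the G of a GYW (the reverse-strand C's sense-strand image).
    """

    motif_class: str  # WRC / GYW / WGCW
    start: int
    end: int
    strand: str  # + / -
    deaminated_site: int
    palindromic: bool = False  # AGCT: overlapping motif on both strands


@dataclass
class TopologyCall:
    """A substitution's relation to the hotspot landscape."""

    event: SubstitutionEvent
    nearest_hit: HotspotHit | None
    distance: int  # nt to the nearest hit interval; 0 = inside
    mechanism_class: str  # canonical_AID / adjacent_AT_noncanonical /
    #                       junction_created / unassociated


def scan_hotspots(nt_seq: str) -> list[HotspotHit]:
    """All WRC, GYW and WGCW occurrences, sorted by start; overlaps kept.

    GYW is scanned on the sense strand as the reverse-strand WRC
    presentation (strand '-').  Raises on non-ACGT input.
    """
    if not is_acgt(nt_seq):
        raise ValueError("hotspot scan requires a non-empty ACGT sequence")
    s = nt_seq
    hits: list[HotspotHit] = []
    for i in range(len(s) - 2):
        a, b, c = s[i], s[i + 1], s[i + 2]
        if a in _W and b in _R and c == "C":
            hits.append(HotspotHit("WRC", i, i + 3, "+", i + 2))
        if a == "G" and b in _Y and c in _W:
            hits.append(HotspotHit("GYW", i, i + 3, "-", i))
    for i in range(len(s) - 3):
        quad = s[i: i + 4]
        if quad[0] in _W and quad[1] == "G" and quad[2] == "C" and quad[3] in _W:
            hits.append(
                HotspotHit("WGCW", i, i + 4, "+", i + 2, palindromic=quad == "AGCT")
            )
    return sorted(hits, key=lambda h: (h.start, h.end, h.motif_class))


def _interval_distance(pos: int, hit: HotspotHit) -> int:
    if hit.start <= pos < hit.end:
        return 0
    if pos < hit.start:
        return hit.start - pos
    return pos - hit.end + 1


def event_nt_position(event: SubstitutionEvent, cdr3_start: int) -> int:
    """Absolute rearrangement coordinate of an event's mutated base."""
    return cdr3_start + 3 * (event.cdr3_position - 1) + event.codon_offset


def classify_mutation_topology(
    event: SubstitutionEvent,
    rearrangement_nt: str,
    cdr3_start: int,
    proximity: int = 2,
    hits: list[HotspotHit] | None = None,
) -> TopologyCall:
    """Relate one substitution to the hotspot landscape of its (unmutated)
    background rearrangement.

    ``rearrangement_nt`` is the pre-mutation sequence the hotspots live on;
    the event's base must match it.  ``proximity`` is the neighbourhood (nt
    from the motif interval) within which an A/T change counts as adjacent.
    """
    pos = event_nt_position(event, cdr3_start)
    if rearrangement_nt[pos] != event.germline_nt:
        raise ValueError(
            f"background base {rearrangement_nt[pos]} at {pos} does not match "
            f"the event's germline nucleotide {event.germline_nt}"
        )
    if hits is None:
        hits = scan_hotspots(rearrangement_nt)
    if not hits:
        return TopologyCall(event, None, -1, "unassociated")
    nearest = min(hits, key=lambda h: (_interval_distance(pos, h), h.start))
    distance = _interval_distance(pos, nearest)
    for h in hits:
        if h.deaminated_site == pos:
            return TopologyCall(event, h, 0, "canonical_AID")
    if rearrangement_nt[pos] in _W and distance <= proximity:
        return TopologyCall(event, nearest, distance, "adjacent_AT_noncanonical")
    return TopologyCall(event, nearest, distance, "unassociated")


def detect_junction_created_hotspots(
    sequence: str,
    nt_labels,
    window: int = 6,
) -> list[HotspotHit]:
    """Hotspots created by V(D)J junction assembly.

    ``nt_labels`` gives each nucleotide's coarse region (V/N1/D/N2/J).  A
    hit is flagged when its interval spans at least two regions and its
    motif string is absent from the corresponding window of the pure
    germline concatenation (the sequence with N-region nucleotides
    removed) — i.e. neither germline alone nor germline-to-germline
    juxtaposition encodes it.
    """
    labels = [_coarse(l) for l in nt_labels]
    germ_idx = [i for i, l in enumerate(labels) if l not in ("N1", "N2")]
    germ_concat = "".join(sequence[i] for i in germ_idx)
    # for each sequence position, how many germline nt lie strictly 5' of it
    germ_before = []
    count = 0
    for i, l in enumerate(labels):
        germ_before.append(count)
        if l not in ("N1", "N2"):
            count += 1
    flagged = []
    for hit in scan_hotspots(sequence):
        spanned = {labels[i] for i in range(hit.start, hit.end)}
        if len(spanned) < 2:
            continue
        motif = sequence[hit.start: hit.end]
        g = germ_before[hit.start]
        lo = max(0, g - window)
        hi = min(len(germ_concat), g + window + len(motif))
        if motif in germ_concat[lo:hi]:
            continue
        flagged.append(hit)
    return flagged


def _coarse(label: str) -> str:
    label = str(label)
    if label.startswith("V"):
        return "V"
    if label.startswith("J"):
        return "J"
    return label


def topology_frame(calls: list[TopologyCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = asdict(c.event)
        row.update(
            mechanism_class=c.mechanism_class,
            distance=c.distance,
            hotspot_class=None if c.nearest_hit is None else c.nearest_hit.motif_class,
            hotspot_start=None if c.nearest_hit is None else c.nearest_hit.start,
        )
        rows.append(row)
    cols = list(SubstitutionEvent.__dataclass_fields__) + [
        "mechanism_class", "distance", "hotspot_class", "hotspot_start"
    ]
    return pd.DataFrame(rows, columns=cols)


def topology_summary(calls_df: pd.DataFrame, cohort_size: int) -> pd.DataFrame:
    """Node table for cohort-level topology reporting: per recurrent
    substitution, the fraction of patients, clonal/subclonal flag, and the
    associated hotspot class."""
    cols = ["cdr3_position", "germline_aa", "observed_aa", "region",
            "patient_fraction", "clonality", "mechanism_class", "hotspot_class"]
    if len(calls_df) == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for (pos, gaa, oaa), grp in calls_df.groupby(
        ["cdr3_position", "germline_aa", "observed_aa"]
    ):
        rows.append(
            dict(
                cdr3_position=pos, germline_aa=gaa, observed_aa=oaa,
                region=grp["region"].iloc[0],
                patient_fraction=grp["sample_id"].nunique() / cohort_size,
                clonality="clonal" if (grp["role"] == "clonal").any() else "subclonal",
                mechanism_class=grp["mechanism_class"].mode().iloc[0],
                hotspot_class=grp["hotspot_class"].mode().iloc[0]
                if grp["hotspot_class"].notna().any() else None,
            )
        )
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["patient_fraction", "cdr3_position"], ascending=[False, True]
    ).reset_index(drop=True)
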