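"""Germline segment model, region conventions, and stereotype archetypes.

The package analyses heavy-chain V(D)J rearrangements whose CDR3 is
delimited IMGT-style: it runs from the codon after the conserved FR3
cysteine (C104) to the codon before the J-region conserved tryptophan
(W118).  CDR3 amino-acid positions are 1-based from the first codon after
the cysteine in all user-facing output; internally every interval is
0-based half-open.

Two stereotype archetypes are provided, mirroring the two major CLL
stereotyped subsets this kind of analysis targets: a subset-#1-like
rearrangement (clan I V gene, IGHD6-19-like D read in frame 1 contributing
the conserved QWL motif at CDR3 positions 4-6, IGHJ4-like J; 13-aa CDR3)
and a subset-#6-like rearrangement (IGHV1-69-like V, IGHD3-16-like D in
frame 2 contributing YDYVWGSY with a valine at CDR3 position 9, IGHJ3-like
J; 21-aa CDR3).  The packaged germline sequences are synthetic stand-ins:
they satisfy the archetype constraint sets and the region-boundary
conventions but are not IMGT alleles.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml
from Bio import SeqIO

from ._seqtools import is_acgt, translate

V_REGION_NAMES = ("fr1", "cdr1", "fr2", "cdr2", "fr3")

#: Region labels a CDR3 codon (or junction nucleotide) can carry.
CDR3_REGIONS = ("V", "N1", "D", "N2", "J")


@dataclass(frozen=True)
class GeneSegment:
    """A germline V, D or J segment with its region coordinate metadata.

    ``region_bounds`` holds, for V segments, the half-open nucleotide
    intervals of FR1..FR3 (anything 3' of fr3 is the junction-contributing
    tail); for J segments the key ``fr4_start`` (offset of the conserved
    W codon); for D segments the key ``reading_frames`` (1-based usable
    frames).
    """

    name: str
    sequence: str
    segment_class: str  # V, D or J
    region_bounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.segment_class not in ("V", "D", "J"):
            raise ValueError(f"{self.name}: segment_class must be V, D or J")
        if not is_acgt(self.sequence):
            raise ValueError(f"{self.name}: sequence must be non-empty uppercase ACGT")
        if self.segment_class == "V":
            prev_end = 0
            for region in V_REGION_NAMES:
                if region not in self.region_bounds:
                    raise ValueError(f"{self.name}: missing V region bound '{region}'")
                start, end = self.region_bounds[region]
                if not (prev_end <= start < end <= len(self.sequence)):
                    raise ValueError(
                        f"{self.name}: region '{region}' interval [{start},{end}) is "
                        "out of order or exceeds the sequence"
                    )
                prev_end = end
            if len(self.sequence) - self.region_bounds["fr3"][1] < 3:
                raise ValueError(
                    f"{self.name}: V segment needs >=3 nt of junction-contributing "
                    "sequence after FR3"
                )
        elif self.segment_class == "J":
            w = self.region_bounds.get("fr4_start")
            if w is None or not (0 <= w <= len(self.sequence) - 3):
                raise ValueError(f"{self.name}: J segment needs a valid fr4_start")
            if translate(self.sequence[w: w + 3]) != "W":
                raise ValueError(f"{self.name}: fr4_start does not point at a W codon")
        else:
            frames = self.region_bounds.get("reading_frames", [1, 2, 3])
            if not frames or not all(f in (1, 2, 3) for f in frames):
                raise ValueError(f"{self.name}: reading_frames must be within 1-3")

    # -- V helpers -------------------------------------------------------
    @property
    def fr3_end(self) -> int:
        return self.region_bounds["fr3"][1]

    @property
    def junction_tail(self) -> str:
        """Nucleotides a V segment contributes 3' of FR3 (post-C104)."""
        return self.sequence[self.fr3_end:]

    @property
    def fr4_start(self) -> int:
        return self.region_bounds["fr4_start"]


class GermlineDB:
    """Collection of validated germline segments keyed by name."""

    def __init__(self, segments: list[GeneSegment]):
        self.segments = {s.name: s for s in segments}
        if len(self.segments) != len(segments):
            raise ValueError("duplicate segment names in germline database")

    def __getitem__(self, name: str) -> GeneSegment:
        return self.segments[name]

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments.values())

    def by_class(self, segment_class: str) -> list[GeneSegment]:
        return [s for s in self if s.segment_class == segment_class]


def load_germline_db(fasta_path: str | Path, bounds_path: str | Path) -> GermlineDB:
    """Load a germline segment FASTA plus its region-boundary sidecar.

    The sidecar (YAML) maps each segment name to its class and named
    intervals; every V record must have a boundary entry, and sequences with
    non-ACGT characters are rejected.
    """
    with open(bounds_path) as fh:
        bounds = yaml.safe_load(fh)
    segments = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        entry = bounds.get(rec.id)
        if entry is None:
            raise ValueError(f"no boundary sidecar entry for segment '{rec.id}'")
        cls = entry.get("class")
        region_bounds = {k: v for k, v in entry.items() if k != "class"}
        segments.append(
            GeneSegment(
                name=rec.id,
                sequence=str(rec.seq).upper(),
                segment_class=cls,
                region_bounds=region_bounds,
            )
        )
    if not segments:
        raise ValueError(f"no records parsed from {fasta_path}")
    return GermlineDB(segments)


def default_db() -> GermlineDB:
    """The packaged synthetic germline database (both archetypes' segments)."""
    data = resources.files("cdr3shm.data")
    with resources.as_file(data / "synthetic_germline.fasta") as fasta, resources.as_file(
        data / "synthetic_germline_bounds.yaml"
    ) as bounds:
        return load_germline_db(fasta, bounds)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Recipe for a stereotyped rearrangement.

    ``constraint_set`` lists (1-based CDR3 position, expected amino acid,
    encoding region) triples that the assembled archetype must satisfy.
    """

    subset_id: str
    v_name: str
    d_name: str
    j_name: str
    d_reading_frame: int
    n1: str
    n2: str
    cdr3_aa_length: int
    constraint_set: tuple = ()


SUBSET1 = ArchetypeSpec(
    subset_id="subset1",
    v_name="IGHV-CLAN1-SYN",
    d_name="IGHD6-19-SYN",
    j_name="IGHJ4-SYN",
    d_reading_frame=1,
    n1="CAG",
    n2="GGTCCTTCTACT",
    cdr3_aa_length=13,
    constraint_set=(
        (2, "R", "V"),
        (4, "Q", "D"),
        (5, "W", "D"),
        (6, "L", "D"),
        (12, "D", "J"),
    ),
)

SUBSET6 = ArchetypeSpec(
    subset_id="subset6",
    v_name="IGHV1-69-SYN",
    d_name="IGHD3-16-SYN",
    j_name="IGHJ3-SYN",
    d_reading_frame=2,
    n1="GGTCC",
    n2="ACTCCTAGGACC",
    cdr3_aa_length=21,
    constraint_set=(
        (2, "R", "V"),
        (9, "V", "D"),
        (19, "F", "J"),
    ),
)

ARCHETYPES = {"subset1": SUBSET1, "subset6": SUBSET6}


@dataclass(frozen=True)
class Archetype:
    """An assembled stereotyped rearrangement with per-nucleotide provenance.

    ``region_of_nt`` labels every nucleotide of ``sequence`` with one of
    V-FR1..V-FR3, V-junction, N1, D, N2, J-CDR3 or J-FR4;
    ``cdr3_start``/``cdr3_end`` delimit the CDR3 (half-open, nt coords).
    """

    spec: ArchetypeSpec
    sequence: str
    region_of_nt: tuple
    cdr3_start: int
    cdr3_end: int

    @property
    def cdr3_nt(self) -> str:
        return self.sequence[self.cdr3_start: self.cdr3_end]

    @property
    def cdr3_aa(self) -> str:
        return translate(self.cdr3_nt)

    @property
    def junction_nt(self) -> str:
        """C104 codon through the W118 codon inclusive."""
        return self.sequence[self.cdr3_start - 3: self.cdr3_end + 3]

    def cdr3_codon_region(self, position: int) -> str:
        """Region label of a 1-based CDR3 codon: majority of its three
        nucleotides' origins; ties go to the 5'-most contributing region."""
        if not 1 <= position <= len(self.cdr3_aa):
            raise ValueError(f"CDR3 position {position} out of range")
        start = self.cdr3_start + 3 * (position - 1)
        labels = [
            _coarse(self.region_of_nt[i]) for i in range(start, start + 3)
        ]
        order = {r: i for i, r in enumerate(CDR3_REGIONS)}
        best = max(
            set(labels), key=lambda r: (labels.count(r), -order[r])
        )
        return best

    def cdr3_region_map(self) -> dict[int, str]:
        return {
            p: self.cdr3_codon_region(p) for p in range(1, len(self.cdr3_aa) + 1)
        }


def _coarse(label: str) -> str:
    if label.startswith("V"):
        return "V"
    if label.startswith("J"):
        return "J"
    return label


def build_archetype(spec: ArchetypeSpec, db: GermlineDB) -> Archetype:
    """Assemble V(FR1->junction)+N1+D+N2+J and validate the constraint set.

    Raises if the assembled junction is out of frame, contains a stop, has
    the wrong CDR3 length, or violates any constraint triple — such a
    failure means the spec (segment choice or N regions) needs revising.
    """
    v, d, j = db[spec.v_name], db[spec.d_name], db[spec.j_name]
    for seg, cls in ((v, "V"), (d, "D"), (j, "J")):
        if seg.segment_class != cls:
            raise ValueError(f"{seg.name} is not a {cls} segment")
    if spec.d_reading_frame not in d.region_bounds.get("reading_frames", [1, 2, 3]):
        raise ValueError(
            f"{d.name} does not allow reading frame {spec.d_reading_frame}"
        )
    seq = v.sequence + spec.n1 + d.sequence + spec.n2 + j.sequence

    labels: list[str] = []
    for region in V_REGION_NAMES:
        start, end = v.region_bounds[region]
        labels += [f"V-{region.upper()}"] * (end - start)
    labels += ["V-junction"] * len(v.junction_tail)
    labels += ["N1"] * len(spec.n1)
    labels += ["D"] * len(d.sequence)
    labels += ["N2"] * len(spec.n2)
    labels += ["J-CDR3"] * j.fr4_start
    labels += ["J-FR4"] * (len(j.sequence) - j.fr4_start)
    assert len(labels) == len(seq)

    cdr3_start = v.fr3_end
    cdr3_end = len(v.sequence) + len(spec.n1) + len(d.sequence) + len(spec.n2) + j.fr4_start
    arc = Archetype(
        spec=spec,
        sequence=seq,
        region_of_nt=tuple(labels),
        cdr3_start=cdr3_start,
        cdr3_end=cdr3_end,
    )

    cdr3_len = cdr3_end - cdr3_start
    if cdr3_len % 3:
        raise ValueError(f"{spec.subset_id}: junction out of frame ({cdr3_len} nt CDR3)")
    aa = translate(seq)
    if "*" in aa:
        raise ValueError(f"{spec.subset_id}: assembled archetype is unproductive")
    if len(arc.cdr3_aa) != spec.cdr3_aa_length:
        raise ValueError(
            f"{spec.subset_id}: CDR3 length {len(arc.cdr3_aa)} != "
            f"declared {spec.cdr3_aa_length}"
        )
    # D reading-frame check: the frame implied by the assembly must match.
    # frame f: translation starts at D nt f-1, i.e. D nt f-1 sits on a codon
    # boundary of the rearrangement.
    d_start = len(v.sequence) + len(spec.n1)
    phase = (d_start - cdr3_start) % 3
    implied_frame = 1 + (3 - phase) % 3
    if implied_frame != spec.d_reading_frame:
        raise ValueError(
            f"{spec.subset_id}: D lies in frame {implied_frame}, spec says "
            f"{spec.d_reading_frame}"
        )
    for pos, expected_aa, region in spec.constraint_set:
        got_aa = arc.cdr3_aa[pos - 1]
        got_region = arc.cdr3_codon_region(pos)
        if got_aa != expected_aa or got_region != region:
            raise ValueError(
                f"{spec.subset_id}: constraint (pos {pos}, {expected_aa}, {region}) "
                f"violated: got ({got_aa}, {got_region}); revise the spec"
            )
    return arc
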