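"""Synthetic paired-end repertoire generator with a truth ledger.

Emulates the sequencing design this analysis targets: one dominant
stereotyped clonotype per sample, low-frequency (~0.1%) subclonal CDR3
variants differing from it by single-nucleotide substitutions,
isotype-switched copies of the same rearrangement, and per-base
substitution error near the 2.4% aggregate rate a PhiX-calibrated MiSeq
run shows.  Amplicons are full V(D)J rearrangements; with 2x300 chemistry
and the compact packaged germline segments every amplicon is double-covered
by its read pair, so paired-end merging can correct most sequencing error.

The error model is substitution-only and quality-linked: a configurable
fraction of bases are low-quality and carry almost all of the error (error
probability per base is the Phred expectation ``10**(-Q/10)``), the rest sit
at a high-quality baseline.  The low-quality fraction is derived so the
aggregate per-base error equals ``error_rate`` exactly in expectation.
"""
from __future__ import annotations

import gzip
import io
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seqtools import decode, encode, revcomp_arr, translate
from .germline import Archetype

ISOTYPES = ("IGM", "IGG", "IGA")
MIN_MERGE_OVERLAP = 30


class _TextGz(io.TextIOWrapper):
    def __init__(self, raw):
        super().__init__(raw, encoding="ascii", newline="")


@dataclass(frozen=True)
class InjectionSpec:
    """One subclonal single-nucleotide variant to spike into a repertoire.

    The addressed base is ``codon_offset`` (0-2) within the codon of the
    1-based CDR3 amino-acid position; ``germline_nt`` guards against
    spec/archetype drift and must match the archetype at that base.
    """

    cdr3_aa_position: int
    germline_nt: str
    mutant_nt: str
    codon_offset: int
    target_frequency: float
    isotypes: tuple = ("IGM",)

    def __post_init__(self) -> None:
        if not 0 < self.target_frequency < 1:
            raise ValueError("target_frequency must be in (0,1)")
        if self.mutant_nt == self.germline_nt:
            raise ValueError("mutant_nt must differ from germline_nt")
        if self.codon_offset not in (0, 1, 2):
            raise ValueError("codon_offset must be 0-2")


@dataclass
class VariantTruth:
    label: str
    cdr3_aa_position: int
    germline_nt: str
    mutant_nt: str
    germline_aa: str
    mutant_aa: str
    target_frequency: float
    realized_count: int = 0


@dataclass
class SimulationTruth:
    """Ledger of what was injected and what the multinomial draw realised."""

    sample_id: str
    isotype: str
    n_reads: int
    error_rate: float
    seed: int
    main_realized_count: int
    main_realized_frequency: float
    variants: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "isotype": self.isotype,
            "n_reads": self.n_reads,
            "error_rate": self.error_rate,
            "seed": self.seed,
            "main_realized_count": self.main_realized_count,
            "main_realized_frequency": self.main_realized_frequency,
            "variants": [vars(v) for v in self.variants],
        }


@dataclass(frozen=True)
class QualityModel:
    """Two-component Phred model: Q_high baseline with occasional Q_low bases.

    ``low_frac=None`` derives the low-quality fraction from the requested
    aggregate error rate; setting it explicitly decouples qualities from the
    error rate (useful for exercising quality filters without errors).
    """

    q_high: int = 37
    q_low: int = 5
    low_frac: float | None = None

    def resolve_low_frac(self, error_rate: float) -> float:
        if self.low_frac is not None:
            return self.low_frac
        e_low = 10 ** (-self.q_low / 10)
        e_high = 10 ** (-self.q_high / 10)
        if error_rate <= e_high:
            return 0.0
        return min(1.0, (error_rate - e_high) / (e_low - e_high))


@dataclass
class SimulatedSample:
    """In-memory paired-end output for one sample+isotype.

    ``r1``/``r2`` are (n_reads, read_len) uint8 ASCII base matrices;
    ``q1``/``q2`` the matching Phred scores.  ``write()`` materialises
    gzipped Phred+33 FASTQ.
    """

    sample_id: str
    isotype: str
    r1: np.ndarray
    q1: np.ndarray
    r2: np.ndarray
    q2: np.ndarray
    truth: SimulationTruth

    @property
    def n_reads(self) -> int:
        return self.r1.shape[0]

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for mate, seqs, quals in (("R1", self.r1, self.q1), ("R2", self.r2, self.q2)):
            path = outdir / f"{self.sample_id}_{self.isotype}_{mate}.fastq.gz"
            # mtime=0 keeps the gzip container byte-identical across runs
            with gzip.GzipFile(path, "wb", mtime=0) as raw, _TextGz(raw) as fh:
                for i in range(self.n_reads):
                    fh.write(
                        f"@{self.sample_id}:{self.isotype}:{i} {mate}\n"
                        f"{decode(seqs[i])}\n+\n"
                        f"{(quals[i] + 33).tobytes().decode('ascii')}\n"
                    )
            paths.append(path)
        return tuple(paths)


def inject_variant(archetype: Archetype, spec: InjectionSpec) -> tuple[str, tuple[str, str]]:
    """Apply one substitution to the archetype rearrangement.

    Returns the variant nucleotide sequence (differing at exactly one base)
    and the induced amino-acid change ``(germline_aa, mutant_aa)`` from
    translating the affected codon.  Raises if ``germline_nt`` does not
    match the archetype at the addressed base.
    """
    if not 1 <= spec.cdr3_aa_position <= len(archetype.cdr3_aa):
        raise ValueError(
            f"CDR3 position {spec.cdr3_aa_position} outside 1..{len(archetype.cdr3_aa)}"
        )
    codon_start = archetype.cdr3_start + 3 * (spec.cdr3_aa_position - 1)
    pos = codon_start + spec.codon_offset
    if archetype.sequence[pos] != spec.germline_nt.upper():
        raise ValueError(
            f"germline_nt mismatch at rearrangement position {pos}: archetype has "
            f"{archetype.sequence[pos]}, spec says {spec.germline_nt}"
        )
    seq = archetype.sequence
    variant = seq[:pos] + spec.mutant_nt.upper() + seq[pos + 1:]
    germ_codon = seq[codon_start: codon_start + 3]
    mut_codon = variant[codon_start: codon_start + 3]
    return variant, (translate(germ_codon), translate(mut_codon))


def simulate_repertoire(
    archetype: Archetype,
    injections: list[InjectionSpec],
    n_reads: int,
    error_rate: float = 0.024,
    read_length: int = 300,
    quality_model: QualityModel | None = None,
    seed: int = 0,
    sample_id: str = "sample1",
    isotype: str = "IGM",
) -> SimulatedSample:
    """Draw a paired-end repertoire for one sample and isotype.

    Each read pair derives from the archetype or one injected variant via a
    multinomial draw at the target frequencies; substitution errors are
    independent per base.  Deterministic under a fixed seed.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0,1)")
    qm = quality_model or QualityModel()
    L = len(archetype.sequence)
    rl = min(read_length, L)
    junction_start = archetype.cdr3_start - 3
    junction_end = archetype.cdr3_end + 3
    if rl < junction_end or L - rl > junction_start or 2 * rl - L < MIN_MERGE_OVERLAP:
        raise ValueError(
            f"read_length {read_length} cannot cover the junction of a {L} nt "
            "amplicon with sufficient overlap"
        )

    templates = [encode(archetype.sequence)]
    probs = [1.0 - sum(i.target_frequency for i in injections)]
    truth_variants = []
    for k, inj in enumerate(injections):
        var_seq, (gaa, maa) = inject_variant(archetype, inj)
        templates.append(encode(var_seq))
        probs.append(inj.target_frequency)
        truth_variants.append(
            VariantTruth(
                label=f"var{k + 1}_pos{inj.cdr3_aa_position}_{gaa}>{maa}",
                cdr3_aa_position=inj.cdr3_aa_position,
                germline_nt=inj.germline_nt,
                mutant_nt=inj.mutant_nt,
                germline_aa=gaa,
                mutant_aa=maa,
                target_frequency=inj.target_frequency,
            )
        )
    if probs[0] <= 0:
        raise ValueError("injection target frequencies sum to >= 1")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, probs)
    assign = np.repeat(np.arange(len(templates)), counts)
    tmpl = np.stack(templates)  # (k+1, L)
    amplicons = tmpl[assign]  # (n, L)

    r1 = amplicons[:, :rl].copy()
    r2 = revcomp_arr(amplicons[:, L - rl:]).copy()

    low_frac = qm.resolve_low_frac(error_rate)
    out = []
    for mate in (r1, r2):
        q = np.full(mate.shape, qm.q_high, dtype=np.uint8)
        if low_frac > 0:
            low = rng.random(mate.shape) < low_frac
            q[low] = qm.q_low
        if error_rate > 0:
            perr = np.where(q >= qm.q_high, 10.0 ** (-qm.q_high / 10), 10.0 ** (-qm.q_low / 10))
            if low_frac == 0.0:
                perr = np.full(mate.shape, error_rate)
            err = rng.random(mate.shape) < perr
            _apply_errors(mate, err, rng)
        out.append(q)
    q1, q2 = out

    main_count = int(counts[0])
    truth = SimulationTruth(
        sample_id=sample_id,
        isotype=isotype,
        n_reads=n_reads,
        error_rate=error_rate,
        seed=seed,
        main_realized_count=main_count,
        main_realized_frequency=main_count / n_reads,
    )
    for v, c in zip(truth_variants, counts[1:]):
        v.realized_count = int(c)
        truth.variants.append(v)
    return SimulatedSample(sample_id, isotype, r1, q1, r2, q2, truth)


def _apply_errors(mate: np.ndarray, err: np.ndarray, rng: np.random.Generator) -> None:
    """Flip erroneous bases to one of the three other bases, uniformly."""
    idx_of = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        idx_of[b] = i
    flat = np.flatnonzero(err)
    if len(flat) == 0:
        return
    cur = idx_of[mate.reshape(-1)[flat]]
    new = (cur + rng.integers(1, 4, size=len(flat))) % 4
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    mate.reshape(-1)[flat] = lut[new]


def derive_seed(master_seed: int, *keys) -> int:
    """Stable per-sample/per-isotype sub-seed below 2**31 (crc32 keying, so
    the derivation is reproducible across processes)."""
    ss = np.random.SeedSequence(
        master_seed, spawn_key=tuple(zlib.crc32(str(k).encode()) for k in keys)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    archetype: Archetype,
    injections_per_sample: dict,
    n_reads: int,
    error_rate: float = 0.024,
    seed: int = 0,
    isotypes: tuple = ("IGM",),
    **kwargs,
) -> dict:
    """Simulate several samples (optionally several isotypes each).

    ``injections_per_sample`` maps sample_id -> list of InjectionSpec.  An
    injection is emitted for a given isotype only if that isotype is listed
    in its ``isotypes`` field; switched (IGG/IGA) reads reuse the same
    nucleotide rearrangement.  Returns {(sample_id, isotype): SimulatedSample}.
    """
    out = {}
    for sample_id, injections in injections_per_sample.items():
        for iso in isotypes:
            inj = [i for i in injections if iso in i.isotypes]
            out[(sample_id, iso)] = simulate_repertoire(
                archetype,
                inj,
                n_reads=n_reads,
                error_rate=error_rate,
                seed=derive_seed(seed, sample_id, iso),
                sample_id=sample_id,
                isotype=iso,
                **kwargs,
            )
    return out


def write_truth(samples: dict, outdir: str | Path) -> Path:
    """Write the cohort truth ledger as JSON (plus a flat TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {f"{sid}:{iso}": s.truth.to_dict() for (sid, iso), s in samples.items()}
    jpath = outdir / "truth.json"
    jpath.write_text(json.dumps(payload, indent=2))
    rows = ["sample_id\tisotype\tlabel\tcdr3_aa_position\tgermline_aa\tmutant_aa\t"
            "target_frequency\trealized_count"]
    for (sid, iso), s in samples.items():
        for v in s.truth.variants:
            rows.append(
                f"{sid}\t{iso}\t{v.label}\t{v.cdr3_aa_position}\t{v.germline_aa}\t"
                f"{v.mutant_aa}\t{v.target_frequency}\t{v.realized_count}"
            )
    (outdir / "truth.tsv").write_text("\n".join(rows) + "\n")
    return jpath


def simulate_position_frequencies(
    n_samples: int,
    n_positions: int,
    baseline: float = 0.001,
    elevated_positions: tuple = (),
    fold: float = 10.0,
    sigma: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Cohort-level per-sample per-position mutation-frequency matrix.

    Log-normal variation around ``baseline`` (median per-position subclonal
    frequency ~0.1%, matching the regime the pipeline reports), with the
    listed 1-based positions elevated ``fold``-fold.  Used by the rank-based
    positional-targeting statistics and their power/type-I simulations.
    """
    rng = rng or np.random.default_rng()
    m = baseline * np.exp(rng.normal(0.0, sigma, size=(n_samples, n_positions)))
    for p in elevated_positions:
        m[:, p - 1] *= fold
    return m
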