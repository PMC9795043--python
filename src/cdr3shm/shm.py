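"""Per-position CDR3 substitution profiling and the cohort statistics.

Substitution calling convention: at germline-encoded CDR3 positions
(V-, D- or J-templated codons) variants are compared against the germline
translation; at N-region positions — where no germline exists — they are
compared against the main variant, and pure-N differences are reported but
not classed as SHM.  Each amino-acid difference of a variant yields one
event carrying the underlying nucleotide change (recovered from the codon
diff), its transition/transversion class, the encoding region and the
variant's frequency.

Cohort statistics follow the rank-based recipe standard for small AIRR
cohorts: a Kruskal-Wallis omnibus across CDR3 positions on per-sample
mutation frequencies, Wilcoxon rank-sum post-hoc tests of each position
against the pooled remaining positions (one-sided: preferential targeting
means *elevated* frequency), Holm-Bonferroni adjustment, alpha = 0.05; and
a two-sided Mann-Whitney U test for comparing subclonal heterogeneity
between two stereotyped subsets (exact enumeration at small n).
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._seqtools import PURINES, PYRIMIDINES, translate

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SubstitutionEvent:
    """One CDR3 substitution carried by a (sub)clonal variant."""

    sample_id: str
    cdr3_position: int  # 1-based
    germline_aa: str
    observed_aa: str
    germline_nt: str
    observed_nt: str
    codon_offset: int
    region: str  # V / N1 / D / N2 / J
    change_class: str  # transition / transversion
    frequency: float
    isotype: str = ""
    role: str = "subclonal"  # or clonal (main-vs-germline)
    synonymous: bool = False


def classify_nt_change(ref_nt: str, alt_nt: str) -> str:
    """Transition iff both bases are purines or both pyrimidines."""
    ref, alt = ref_nt.upper(), alt_nt.upper()
    if ref == alt:
        raise ValueError("ref and alt nucleotides are identical")
    if {ref, alt} <= PURINES or {ref, alt} <= PYRIMIDINES:
        return "transition"
    return "transversion"


def profile_substitutions(
    main: pd.Series,
    variants: pd.DataFrame,
    include_main_vs_germline: bool = True,
) -> list[SubstitutionEvent]:
    """Diff each variant's CDR3 against the germline-anchored reference.

    ``main`` and ``variants`` are clonotype rows carrying ``cdr3_aa``,
    junction-derived ``germline_cdr3_ref`` (germline bases at templated
    positions, the read's own bases at N positions), ``cdr3_region_map``
    and ``frequency``.  The reference CDR3 equals the germline bases at
    V/D/J positions and the *main variant's* bases at N positions.  Events
    from the same variant share its frequency; synonymous nucleotide-only
    differences are recorded with ``synonymous=True``.  With
    ``include_main_vs_germline`` the main variant itself is diffed against
    germline, yielding role=``clonal`` events.
    """
    region_map = main["cdr3_region_map"]
    if region_map is None:
        raise ValueError("main variant lacks a CDR3 region map")
    ref_nt = _reference_cdr3(main)
    ref_aa = translate(ref_nt)
    events: list[SubstitutionEvent] = []

    def diff(row: pd.Series, role: str) -> None:
        var_nt = _variant_cdr3_nt(row)
        if var_nt is None:
            return
        if len(var_nt) != len(ref_nt):
            raise ValueError(
                "variant/main CDR3 length mismatch; variants must be "
                "pre-filtered to the main CDR3 length"
            )
        var_aa = translate(var_nt)
        for p in range(len(ref_aa)):
            codon_ref = ref_nt[3 * p: 3 * p + 3]
            codon_var = var_nt[3 * p: 3 * p + 3]
            if codon_ref == codon_var:
                continue
            off = next(i for i in range(3) if codon_ref[i] != codon_var[i])
            events.append(
                SubstitutionEvent(
                    sample_id=str(row.get("sample_id", main.get("sample_id", ""))),
                    cdr3_position=p + 1,
                    germline_aa=ref_aa[p],
                    observed_aa=var_aa[p],
                    germline_nt=codon_ref[off],
                    observed_nt=codon_var[off],
                    codon_offset=off,
                    region=region_map[p + 1],
                    change_class=classify_nt_change(codon_ref[off], codon_var[off]),
                    frequency=float(row["frequency"]),
                    isotype=str(row.get("isotype", "")),
                    role=role,
                    synonymous=ref_aa[p] == var_aa[p],
                )
            )

    if include_main_vs_germline:
        diff(main, "clonal")
    for _, row in variants.iterrows():
        if row["sequence"] == main["sequence"]:
            continue
        diff(row, "subclonal")
    return events


def _reference_cdr3(main: pd.Series) -> str:
    """Germline bases at templated positions, main's bases at N positions."""
    ref = main.get("germline_cdr3_ref")
    if not isinstance(ref, str):
        raise ValueError("main variant lacks germline_cdr3_ref")
    return ref


def _variant_cdr3_nt(row: pd.Series) -> str | None:
    junction = row.get("junction") or row.get("junction_nt")
    if isinstance(junction, str) and len(junction) >= 6:
        return junction[3:-3]
    return None


def events_to_frame(events: list[SubstitutionEvent]) -> pd.DataFrame:
    cols = list(SubstitutionEvent.__dataclass_fields__)
    if not events:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([asdict(e) for e in events], columns=cols)


def recurrence_report(
    events: pd.DataFrame,
    cohort_size: int,
    min_samples: int = 2,
    include_synonymous: bool = False,
) -> pd.DataFrame:
    """Cross-sample recurrence of identical substitutions.

    Groups events by (CDR3 position, germline aa -> observed aa) and
    reports how many samples of the cohort carry the event, the cohort
    fraction, and the median/min/max of the per-sample frequencies.
    """
    cols = ["cdr3_position", "germline_aa", "observed_aa", "region",
            "change_class", "n_samples", "cohort_fraction",
            "median_frequency", "min_frequency", "max_frequency"]
    if len(events) == 0:
        return pd.DataFrame(columns=cols)
    df = events if include_synonymous else events[~events["synonymous"]]
    rows = []
    for (pos, gaa, oaa), grp in df.groupby(
        ["cdr3_position", "germline_aa", "observed_aa"]
    ):
        per_sample = grp.groupby("sample_id")["frequency"].sum()
        n = per_sample.index.nunique()
        if n < min_samples:
            continue
        rows.append(
            dict(
                cdr3_position=pos, germline_aa=gaa, observed_aa=oaa,
                region=grp["region"].iloc[0],
                change_class=grp["change_class"].iloc[0],
                n_samples=n, cohort_fraction=n / cohort_size,
                median_frequency=float(per_sample.median()),
                min_frequency=float(per_sample.min()),
                max_frequency=float(per_sample.max()),
            )
        )
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(
        ["n_samples", "cdr3_position"], ascending=[False, True]
    ).reset_index(drop=True)


def holm_bonferroni(pvals) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def positional_targeting_test(
    frequencies: np.ndarray | pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Rank-based test for preferentially targeted CDR3 positions.

    ``frequencies`` is a samples x positions matrix of per-sample
    per-position mutation frequencies (a sample's value at a position is
    the summed frequency of its subclonal variants mutated there).
    Kruskal-Wallis across positions; if the omnibus p < alpha, each
    position is compared against the pooled remaining positions with a
    one-sided Wilcoxon rank-sum test (alternative: greater), and the
    post-hoc family is Holm-adjusted.  Returns omnibus p, per-position
    adjusted p (NaN when the omnibus gate fails), and the flagged 1-based
    positions.
    """
    if isinstance(frequencies, pd.DataFrame):
        frequencies = frequencies.to_numpy()
    m = np.asarray(frequencies, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 positions")
    n_samples, n_pos = m.shape
    groups = [m[:, j] for j in range(n_pos)]
    if np.all(m == m.flat[0]):
        return {"omnibus_p": 1.0, "adjusted_p": np.full(n_pos, np.nan),
                "flagged_positions": []}
    omnibus_p = float(stats.kruskal(*groups).pvalue)
    adj = np.full(n_pos, np.nan)
    flagged: list[int] = []
    if omnibus_p < alpha:
        raw = np.empty(n_pos)
        for j in range(n_pos):
            rest = np.delete(m, j, axis=1).ravel()
            raw[j] = stats.mannwhitneyu(
                m[:, j], rest, alternative="greater", method="asymptotic"
            ).pvalue
        adj = holm_bonferroni(raw)
        flagged = [j + 1 for j in range(n_pos) if adj[j] < alpha]
    return {"omnibus_p": omnibus_p, "adjusted_p": adj, "flagged_positions": flagged}


def compare_heterogeneity(counts_a, counts_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing subclonal-variant counts.

    Exact enumeration when both groups have n <= 8 and no ties across
    groups; tie-corrected normal approximation (no continuity correction,
    so identical samples give p = 1) otherwise.  Returns (U, p).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) <= 8 and len(b) <= 8 and not ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def position_frequency_matrix(
    main: pd.Series, variants: pd.DataFrame
) -> pd.DataFrame:
    """Read-weighted per-position amino-acid frequency matrix.

    Rows are 1-based CDR3 positions, columns the 20 amino acids; each row
    sums to 1.  Input rows need ``cdr3_aa`` and ``read_count``.
    """
    seqs, weights = [main["cdr3_aa"]], [float(main["read_count"])]
    for _, row in variants.iterrows():
        if row["sequence"] == main["sequence"]:
            continue
        if isinstance(row["cdr3_aa"], str) and len(row["cdr3_aa"]) == len(main["cdr3_aa"]):
            seqs.append(row["cdr3_aa"])
            weights.append(float(row["read_count"]))
    L = len(main["cdr3_aa"])
    mat = np.zeros((L, len(AMINO_ACIDS)))
    col = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for s, w in zip(seqs, weights):
        for p, aa in enumerate(s):
            mat[p, col[aa]] += w
    mat /= mat.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        mat, index=pd.RangeIndex(1, L + 1, name="cdr3_position"),
        columns=list(AMINO_ACIDS),
    )


def per_sample_position_frequencies(
    events: pd.DataFrame, n_positions: int, samples: list[str]
) -> pd.DataFrame:
    """Samples x positions matrix: summed subclonal frequencies of variants
    mutated at each position (non-synonymous events only)."""
    m = pd.DataFrame(0.0, index=samples, columns=range(1, n_positions + 1))
    if len(events) == 0:
        return m
    df = events[(~events["synonymous"]) & (events["role"] == "subclonal")]
    for (sid, pos), grp in df.groupby(["sample_id", "cdr3_position"]):
        if sid in m.index and pos in m.columns:
            m.at[sid, pos] = grp["frequency"].sum()
    return m
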