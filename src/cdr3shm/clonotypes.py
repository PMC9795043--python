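"""Clonotype computation and subclonal/switched variant calling.

Definitions implemented here: a *clonotype* is a unique nucleotide V(D)J
rearrangement sequence; the *main variant* is the clonotype holding the
majority of a sample's reads; *subclonal variants* share the main's V gene
and CDR3 amino-acid length and differ from it by at most two amino acids
(zero allowed: synonymous nucleotide variants); *switched variants* are the
same rearrangement observed in a gamma or alpha transcript.  A read-count
cutoff (default 66, the coverage limit for ~2.4% sequencing error) guards
against error-derived artefact clonotypes, with an optional exception for
below-cutoff variants carrying the germline residue at a clonally mutated
position.  The *truly unmutated* filter keeps only clonotypes with exactly
100% germline V identity across FR1-FR3.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

CLONOTYPE_COLUMNS = [
    "sequence", "read_count", "frequency", "v_call", "d_call", "j_call",
    "cdr3_aa", "v_identity", "isotype", "productive",
]


def compute_clonotypes(annotated: pd.DataFrame) -> pd.DataFrame:
    """Collapse an annotated (productive) read table into clonotypes.

    One row per unique nucleotide rearrangement; ``read_count`` is the
    multiplicity (summing ``duplicate_count`` when present), ``frequency``
    the fraction of the sample's productive reads.  Sorted by count
    descending, ties lexicographically by sequence.
    """
    if len(annotated) == 0:
        return pd.DataFrame(columns=CLONOTYPE_COLUMNS)
    df = annotated[annotated["productive"].astype(bool)].copy()
    if len(df) == 0:
        return pd.DataFrame(columns=CLONOTYPE_COLUMNS)
    if "duplicate_count" not in df:
        df["duplicate_count"] = 1
    agg = {
        "duplicate_count": "sum",
        "v_call": "first",
        "d_call": "first",
        "j_call": "first",
        "cdr3_aa": "first",
        "v_identity": "first",
        "productive": "first",
    }
    if "isotype" in df:
        agg["isotype"] = "first"
    for extra in ("cdr3_region_map", "germline_cdr3_ref", "junction", "cdr3_start"):
        if extra in df:
            agg[extra] = "first"
    out = df.groupby("sequence", as_index=False).agg(agg)
    out = out.rename(columns={"duplicate_count": "read_count"})
    total = int(out["read_count"].sum())
    out["frequency"] = out["read_count"] / total
    out = out.sort_values(
        ["read_count", "sequence"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def identify_main_variant(table: pd.DataFrame) -> pd.Series:
    """The top-count clonotype; exact ties resolve to the lexicographically
    smallest sequence and are logged as a warning."""
    if len(table) == 0:
        raise ValueError("empty clonotype table has no main variant")
    top = table[table["read_count"] == table["read_count"].max()]
    if len(top) > 1:
        warnings.warn(
            f"main-variant tie at {int(top['read_count'].iloc[0])} reads; "
            "picking lexicographically smallest sequence"
        )
    return top.sort_values("sequence").iloc[0]


def aa_hamming(a: str, b: str) -> int:
    """Positional amino-acid distance between equal-length CDR3 strings."""
    if len(a) != len(b):
        raise ValueError("aa_hamming requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def find_subclonal_variants(table: pd.DataFrame, main: pd.Series) -> pd.DataFrame:
    """Assign roles: main / subclonal (same V gene, same CDR3 length,
    <= 2 aa differences from the main) / background."""
    out = table.copy()
    roles, dists = [], []
    for _, row in out.iterrows():
        if row["sequence"] == main["sequence"]:
            roles.append("main")
            dists.append(0)
            continue
        if (
            row["v_call"] == main["v_call"]
            and isinstance(row["cdr3_aa"], str)
            and isinstance(main["cdr3_aa"], str)
            and len(row["cdr3_aa"]) == len(main["cdr3_aa"])
        ):
            d = aa_hamming(row["cdr3_aa"], main["cdr3_aa"])
            if d <= 2:
                roles.append("subclonal")
                dists.append(d)
                continue
        roles.append("background")
        dists.append(np.nan)
    out["role"] = roles
    out["aa_distance_to_main"] = dists
    return out


def apply_read_cutoff(
    table: pd.DataFrame,
    min_reads: int = 66,
    allow_germline_exception: bool = False,
    germline_cdr3_aa: str | None = None,
    main_cdr3_aa: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep clonotypes with read_count >= ``min_reads`` (inclusive bound).

    With the germline exception enabled, a below-cutoff clonotype is
    retained (flagged ``germline_exception=True``) iff it carries the
    germline residue at a position where the main variant is clonally
    mutated away from germline — the rationale being that a germline
    revertant cannot be a sequencing artefact of the mutated main sequence
    pattern alone.  Returns (kept table, discard log).
    """
    if len(table) == 0:
        return table.copy(), table.copy()
    keep = table["read_count"] >= min_reads
    exception = pd.Series(False, index=table.index)
    if allow_germline_exception and germline_cdr3_aa and main_cdr3_aa:
        mutated_positions = [
            i for i, (g, m) in enumerate(zip(germline_cdr3_aa, main_cdr3_aa))
            if g != m
        ]
        for idx in table.index[~keep]:
            aa = table.at[idx, "cdr3_aa"]
            if not isinstance(aa, str) or len(aa) != len(germline_cdr3_aa):
                continue
            if any(aa[i] == germline_cdr3_aa[i] for i in mutated_positions):
                exception[idx] = True
    kept = table[keep | exception].copy()
    kept["germline_exception"] = exception[keep | exception]
    discarded = table[~(keep | exception)].copy()
    return kept, discarded


def filter_truly_unmutated(table: pd.DataFrame) -> pd.DataFrame:
    """Keep clonotypes with exactly 100% V germline identity over FR1-FR3."""
    if len(table) == 0:
        return table.copy()
    return table[table["v_identity"] == 100.0].copy()


def link_switched_variants(
    mu_table: pd.DataFrame,
    gamma_table: pd.DataFrame | None = None,
    alpha_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cross-isotype linkage of the mu repertoire's clonotypes.

    Emits one row per link: the switched clonotype identical in nucleotide
    sequence to the mu main variant (relation ``switched_main``), and, for
    every amino-acid change carried by a mu subclonal variant, any switched
    variant carrying the same change at the same CDR3 position (relation
    ``shared_aa_change``).
    """
    main = identify_main_variant(mu_table)
    links = []
    for iso_name, tab in (("IGG", gamma_table), ("IGA", alpha_table)):
        if tab is None or len(tab) == 0:
            continue
        hit = tab[tab["sequence"] == main["sequence"]]
        for _, row in hit.iterrows():
            links.append(
                dict(isotype=iso_name, relation="switched_main",
                     mu_sequence=main["sequence"], linked_sequence=row["sequence"],
                     detail=f"read_count={int(row['read_count'])}")
            )
        if "role" not in mu_table.columns:
            continue
        sub = mu_table[mu_table["role"] == "subclonal"]
        for _, mu_row in sub.iterrows():
            if not isinstance(mu_row["cdr3_aa"], str):
                continue
            changes = [
                (i + 1, a, b)
                for i, (a, b) in enumerate(zip(main["cdr3_aa"], mu_row["cdr3_aa"]))
                if a != b
            ]
            for pos, ref_aa, alt_aa in changes:
                for _, srow in tab.iterrows():
                    aa = srow["cdr3_aa"]
                    if (
                        isinstance(aa, str)
                        and len(aa) == len(main["cdr3_aa"])
                        and srow["sequence"] != main["sequence"]
                        and aa[pos - 1] == alt_aa
                    ):
                        links.append(
                            dict(isotype=iso_name, relation="shared_aa_change",
                                 mu_sequence=mu_row["sequence"],
                                 linked_sequence=srow["sequence"],
                                 detail=f"{ref_aa}{pos}{alt_aa}")
                        )
    return pd.DataFrame(
        links, columns=["isotype", "relation", "mu_sequence", "linked_sequence", "detail"]
    )
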