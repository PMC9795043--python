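"""Clonotype computation, variant roles, cutoff and isotype linkage."""
import numpy as np
import pandas as pd
import pytest

from cdr3shm.clonotypes import (
    aa_hamming,
    apply_read_cutoff,
    compute_clonotypes,
    filter_truly_unmutated,
    find_subclonal_variants,
    identify_main_variant,
    link_switched_variants,
)


def reads_frame(rows):
    """Annotated-read-like frame: (sequence, cdr3_aa, v_identity, n_copies)."""
    recs = []
    for seq, cdr3, ident, n in rows:
        recs.append(
            dict(sequence=seq, cdr3_aa=cdr3, v_call="V1", d_call="D1", j_call="J1",
                 v_identity=ident, productive=True, duplicate_count=n,
                 isotype="IGM", junction="NNN" + "GCT" * len(cdr3) + "NNN")
        )
    return pd.DataFrame(recs)


class TestComputeClonotypes:
    def test_identical_reads_single_clonotype(self):
        t = compute_clonotypes(reads_frame([("AAA", "K", 100.0, 100)]))
        assert len(t) == 1
        assert t.loc[0, "frequency"] == 1.0

    def test_two_clonotypes_frequencies(self):
        t = compute_clonotypes(
            reads_frame([("AAA", "K", 100.0, 99), ("AAG", "K", 100.0, 1)])
        )
        assert list(t["frequency"]) == [0.99, 0.01]

    def test_synonymous_nt_variants_stay_distinct(self):
        t = compute_clonotypes(
            reads_frame([("AAA", "K", 100.0, 1), ("AAG", "K", 100.0, 1)])
        )
        assert len(t) == 2

    def test_read_count_conservation(self, rng):
        rows = [(f"SEQ{i}", "KK", 100.0, int(rng.integers(1, 50))) for i in range(20)]
        t = compute_clonotypes(reads_frame(rows))
        assert t["read_count"].sum() == sum(r[3] for r in rows)

    def test_empty_input(self):
        t = compute_clonotypes(pd.DataFrame(columns=["sequence", "productive"]))
        assert len(t) == 0


class TestMainVariant:
    def test_unique_top(self):
        t = compute_clonotypes(reads_frame([("A", "K", 100.0, 5), ("C", "K", 100.0, 2)]))
        assert identify_main_variant(t)["sequence"] == "A"

    def test_tie_deterministic_with_warning(self):
        t = compute_clonotypes(reads_frame([("C", "K", 100.0, 5), ("A", "K", 100.0, 5)]))
        with pytest.warns(UserWarning, match="tie"):
            main = identify_main_variant(t)
        assert main["sequence"] == "A"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            identify_main_variant(pd.DataFrame(columns=["read_count"]))


def brute_force_roles(table, main):
    roles = []
    for _, r in table.iterrows():
        if r["sequence"] == main["sequence"]:
            roles.append("main")
        elif (
            r["v_call"] == main["v_call"]
            and len(r["cdr3_aa"]) == len(main["cdr3_aa"])
            and aa_hamming(r["cdr3_aa"], main["cdr3_aa"]) <= 2
        ):
            roles.append("subclonal")
        else:
            roles.append("background")
    return roles


class TestSubclonalVariants:
    @pytest.mark.parametrize(
        "cdr3,expected",
        [
            ("ARQQWLGPSTFDY", "subclonal"),   # 0 aa diff (synonymous nt)
            ("AGQQWLGPSTFDY", "subclonal"),   # 1 aa
            ("AGQRWLGPSTFDY", "subclonal"),   # 2 aa
            ("AGQRWLGPSTFGY", "background"),  # 3 aa
            ("ARQQWLGPSTFD", "background"),   # different length
        ],
    )
    def test_role_rules(self, cdr3, expected):
        t = compute_clonotypes(
            reads_frame([("MAIN", "ARQQWLGPSTFDY", 100.0, 50), ("VAR", cdr3, 100.0, 2)])
        )
        main = identify_main_variant(t)
        t = find_subclonal_variants(t, main)
        assert t.loc[t["sequence"] == "VAR", "role"].iloc[0] == expected

    def test_other_v_gene_is_background(self):
        t = compute_clonotypes(reads_frame([("MAIN", "KKK", 100.0, 50)]))
        other = reads_frame([("VAR", "KKK", 100.0, 2)]).assign(v_call="V2")
        t = pd.concat([t, compute_clonotypes(other)], ignore_index=True)
        main = t.iloc[0]
        t = find_subclonal_variants(t, main)
        assert t.loc[t["sequence"] == "VAR", "role"].iloc[0] == "background"

    @pytest.mark.filterwarnings("ignore:main-variant tie")
    def test_matches_brute_force_on_random_tables(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            n = int(rng.integers(2, 60))
            rows = []
            for i in range(n):
                L = int(rng.choice([5, 5, 5, 6]))
                cdr3 = "".join(rng.choice(list(aas[:4])) for _ in range(L))
                rows.append((f"S{i}", cdr3, 100.0, int(rng.integers(1, 30))))
            t = compute_clonotypes(reads_frame(rows))
            main = identify_main_variant(t)
            got = find_subclonal_variants(t, main)
            assert list(got["role"]) == brute_force_roles(t, main)


class TestReadCutoff:
    def test_inclusive_boundary(self):
        t = compute_clonotypes(
            reads_frame([("A", "K", 100.0, 100), ("C", "K", 100.0, 66), ("G", "K", 100.0, 65)])
        )
        kept, discarded = apply_read_cutoff(t, min_reads=66)
        assert sorted(kept["sequence"]) == ["A", "C"]
        assert list(discarded["sequence"]) == ["G"]

    def test_all_below_cutoff_empty(self):
        t = compute_clonotypes(reads_frame([("A", "K", 100.0, 5)]))
        kept, _ = apply_read_cutoff(t, min_reads=66)
        assert len(kept) == 0

    def test_germline_revertant_exception(self):
        # main carries a clonal V>I change; a 33-read variant restores the
        # germline V and is retained despite the cutoff
        t = compute_clonotypes(
            reads_frame([("MAIN", "AIK", 100.0, 1000), ("REV", "AVK", 100.0, 33)])
        )
        kept, _ = apply_read_cutoff(
            t, min_reads=66, allow_germline_exception=True,
            germline_cdr3_aa="AVK", main_cdr3_aa="AIK",
        )
        assert "REV" in set(kept["sequence"])
        assert bool(kept.loc[kept["sequence"] == "REV", "germline_exception"].iloc[0])
        kept2, _ = apply_read_cutoff(t, min_reads=66)
        assert "REV" not in set(kept2["sequence"])


class TestTrulyUnmutated:
    def test_exact_identity_required(self):
        t = compute_clonotypes(
            reads_frame([("A", "K", 100.0, 10), ("C", "K", 99.6, 10), ("G", "K", 100.0, 1)])
        )
        kept = filter_truly_unmutated(t)
        assert set(kept["sequence"]) == {"A", "G"}


class TestSwitchedVariants:
    def _mu(self):
        t = compute_clonotypes(
            reads_frame([("MAIN", "ARQQWLGPSTFDY", 100.0, 900),
                         ("VARG", "AGQQWLGPSTFDY", 100.0, 80)])
        )
        main = identify_main_variant(t)
        return find_subclonal_variants(t, main)

    def test_switched_main_linked(self):
        gamma = compute_clonotypes(reads_frame([("MAIN", "ARQQWLGPSTFDY", 100.0, 40)]))
        links = link_switched_variants(self._mu(), gamma_table=gamma)
        assert (links["relation"] == "switched_main").sum() == 1

    def test_empty_switched_tables(self):
        links = link_switched_variants(self._mu(), gamma_table=pd.DataFrame())
        assert len(links) == 0

    def test_shared_aa_change_detected(self):
        gamma = compute_clonotypes(
            reads_frame([("MAIN", "ARQQWLGPSTFDY", 100.0, 40),
                         ("GVAR", "AGQQWLGPSTFDY", 100.0, 5)])
        )
        links = link_switched_variants(self._mu(), gamma_table=gamma)
        shared = links[links["relation"] == "shared_aa_change"]
        assert len(shared) == 1
        assert shared["detail"].iloc[0] == "R2G"
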