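"""Substitution profiling, recurrence, and the rank-based statistics."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cdr3shm.clonotypes import compute_clonotypes, find_subclonal_variants, identify_main_variant
from cdr3shm.pipeline import process_simulated_sample
from cdr3shm.shm import (
    classify_nt_change,
    compare_heterogeneity,
    events_to_frame,
    holm_bonferroni,
    per_sample_position_frequencies,
    position_frequency_matrix,
    positional_targeting_test,
    profile_substitutions,
    recurrence_report,
)
from cdr3shm.simulate import (
    InjectionSpec,
    simulate_position_frequencies,
    simulate_repertoire,
)


class TestClassifyNtChange:
    def test_a_to_g_is_transition(self):
        assert classify_nt_change("A", "G") == "transition"

    def test_t_to_g_is_transversion(self):
        assert classify_nt_change("T", "G") == "transversion"

    def test_partition_of_all_twelve_pairs(self):
        classes = [
            classify_nt_change(a, b)
            for a, b in itertools.permutations("ACGT", 2)
        ]
        assert classes.count("transition") == 4
        assert classes.count("transversion") == 8

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_nt_change("A", "A")


def _profiled_sample(arc1, db, injections, n_reads=4000, seed=5):
    s = simulate_repertoire(arc1, injections, n_reads=n_reads, error_rate=0.0, seed=seed)
    return process_simulated_sample(s, db)


class TestProfileSubstitutions:
    def test_injected_position2_event(self, arc1, db):
        res = _profiled_sample(arc1, db, [InjectionSpec(2, "A", "G", 0, 0.05)])
        ev = res.events[res.events["role"] == "subclonal"]
        assert len(ev) == 1
        row = ev.iloc[0]
        assert (row["cdr3_position"], row["germline_aa"], row["observed_aa"]) == (2, "R", "G")
        assert row["region"] == "V" and row["change_class"] == "transition"
        assert row["frequency"] == pytest.approx(0.05, abs=0.02)

    def test_synonymous_variant_recorded_as_such(self, arc1, db):
        # CTA -> TTA at CDR3 pos 6 (L -> L)
        res = _profiled_sample(
            arc1, db, [InjectionSpec(6, "T", "C", 0, 0.05)], seed=6
        )
        ev = res.events[res.events["role"] == "subclonal"]
        assert len(ev) == 1
        assert bool(ev["synonymous"].iloc[0])
        assert ev["germline_aa"].iloc[0] == ev["observed_aa"].iloc[0] == "L"

    def test_two_aa_variant_shares_frequency(self, arc1, db):
        res = _profiled_sample(
            arc1, db,
            [InjectionSpec(2, "A", "G", 0, 0.04)], seed=7,
        )
        # craft a second variant carrying two changes via direct tables:
        main = res.main
        var = main.copy()
        j = main["junction"]
        cdr3 = j[3:-3]
        # a>g at pos-2 codon (AGA, offset 0) and pos-12 codon (GAC, offset 1)
        mutated = cdr3[:3] + "G" + cdr3[4:34] + "G" + cdr3[35:]
        var["sequence"] = "X" + main["sequence"][1:]
        var["junction"] = j[:3] + mutated + j[-3:]
        var["frequency"] = 0.01
        var["cdr3_aa"] = None
        events = profile_substitutions(main, pd.DataFrame([var]),
                                       include_main_vs_germline=False)
        assert len(events) == 2
        assert {e.frequency for e in events} == {0.01}

    def test_length_mismatch_raises(self, arc1, db):
        res = _profiled_sample(arc1, db, [], seed=8)
        main = res.main
        bad = main.copy()
        bad["sequence"] = "Y" + main["sequence"][1:]
        bad["junction"] = main["junction"][:-3]
        with pytest.raises(ValueError, match="length"):
            profile_substitutions(main, pd.DataFrame([bad]),
                                  include_main_vs_germline=False)


class TestRecurrence:
    def _events(self, n_samples, pos=2, freq=0.001):
        rows = []
        for i in range(n_samples):
            rows.append(dict(
                sample_id=f"P{i}", cdr3_position=pos, germline_aa="R",
                observed_aa="G", germline_nt="A", observed_nt="G",
                codon_offset=0, region="V", change_class="transition",
                frequency=freq, isotype="IGM", role="subclonal", synonymous=False,
            ))
        return pd.DataFrame(rows)

    def test_universal_recurrence(self):
        rep = recurrence_report(self._events(12), cohort_size=12)
        assert len(rep) == 1
        assert rep.loc[0, "n_samples"] == 12
        assert rep.loc[0, "cohort_fraction"] == 1.0

    def test_single_sample_excluded(self):
        rep = recurrence_report(self._events(1), cohort_size=12, min_samples=2)
        assert len(rep) == 0

    def test_partial_cohort_fraction(self):
        rep = recurrence_report(self._events(8), cohort_size=12)
        assert rep.loc[0, "cohort_fraction"] == pytest.approx(8 / 12)


class TestHolmBonferroni:
    def test_worked_example(self):
        assert np.allclose(holm_bonferroni([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.3])[0] == 0.3

    def test_cap_and_monotonicity(self):
        adj = holm_bonferroni([0.6, 0.7, 0.8])
        assert np.all(adj <= 1.0)
        assert np.all(np.diff(np.sort(adj)) >= 0)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(25):
            p = rng.random(int(rng.integers(1, 12)))
            _, ref, _, _ = multipletests(p, method="holm")
            assert np.allclose(holm_bonferroni(p), ref)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
    def test_permutation_invariance(self, pvals):
        perm = list(reversed(pvals))
        a = holm_bonferroni(pvals)
        b = holm_bonferroni(perm)
        assert np.allclose(sorted(a), sorted(b))


def mann_whitney_exact_enumeration(a, b):
    """Oracle: two-sided exact p by enumerating all group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y) + \
            0.5 * sum(1 for x in group_a for y in group_b if x == y)

    u_obs = u_stat(a, b)
    mean = n_a * len(b) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(ga, gb)
        total += 1
        if abs(u - mean) >= abs(u_obs - mean) - 1e-12:
            count += 1
    return count / total


class TestCompareHeterogeneity:
    def test_disjoint_groups_exact_p(self):
        u, p = compare_heterogeneity([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = compare_heterogeneity([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(12):
            a = rng.choice(100, size=3, replace=False).tolist()
            b = rng.choice(np.arange(100, 200), size=3, replace=False).tolist()
            _, p = compare_heterogeneity(a, b)
            assert p == pytest.approx(mann_whitney_exact_enumeration(a, b))

    def test_subset_count_regime_separates(self, rng):
        # subclonal-variant counts near the two subsets' medians (22 vs 7)
        hits = 0
        for k in range(20):
            r = np.random.default_rng(k)
            a = r.poisson(22, size=12)
            b = r.poisson(7, size=4)
            _, p = compare_heterogeneity(a, b)
            hits += p < 0.05
        assert hits >= 18


class TestPositionalTargeting:
    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            positional_targeting_test(np.ones((1, 13)))

    def test_all_zero_convention(self):
        out = positional_targeting_test(np.zeros((5, 13)))
        assert out["omnibus_p"] == 1.0
        assert out["flagged_positions"] == []

    def test_elevated_positions_flagged(self):
        rng = np.random.default_rng(4)
        m = simulate_position_frequencies(
            12, 13, elevated_positions=(2, 4, 12), fold=10, rng=rng
        )
        out = positional_targeting_test(m)
        assert out["omnibus_p"] < 0.05
        assert out["flagged_positions"] == [2, 4, 12]


class TestPositionFrequencyMatrix:
    def test_main_only_is_one_hot(self, arc1, db):
        res = _profiled_sample(arc1, db, [], seed=9)
        pfm = position_frequency_matrix(res.main, res.truly_unmutated)
        assert np.allclose(pfm.sum(axis=1), 1.0)
        for p, aa in enumerate(res.main["cdr3_aa"], start=1):
            assert pfm.loc[p, aa] == 1.0

    def test_low_frequency_variant_cell(self, arc1, db):
        res = _profiled_sample(
            arc1, db, [InjectionSpec(2, "A", "G", 0, 0.001)],
            n_reads=100_000, seed=10,
        )
        pfm = position_frequency_matrix(res.main, res.truly_unmutated)
        assert pfm.loc[2, "G"] == pytest.approx(0.001, rel=0.5)
        assert np.allclose(pfm.sum(axis=1), 1.0)


class TestPerSamplePositionFrequencies:
    def test_sums_variant_frequencies(self):
        ev = events_to_frame([])
        m = per_sample_position_frequencies(ev, 13, ["P0"])
        assert m.shape == (1, 13) and (m == 0).all().all()
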