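"""Ortholog mapping, Venn partition of DEOs, Fisher enrichment."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from symcell.orthologs import (fisher_enrichment, map_orthologs,
                               validate_ortholog_table, venn_partition)
from symcell.validation import enumerate_small_tables, fisher_two_sided_oracle


def _table(rows):
    return pd.DataFrame(rows, columns=["gene_a", "orthogroup", "gene_b"])


def test_map_orthologs_basic_and_dedup():
    table = _table([("a1", "OG7", "b1"), ("a2", "OG7", "b2"),
                    ("a3", "OG9", "b3")])
    assert map_orthologs(["a1"], table, "a") == {"OG7"}
    assert map_orthologs(["a1", "a2"], table, "a") == {"OG7"}
    assert map_orthologs(["b3", "b_unknown"], table, "b") == {"OG9"}
    assert map_orthologs([], table, "a") == set()


def test_ortholog_table_invariants():
    with pytest.raises(ValueError, match="empty"):
        map_orthologs(["a1"], _table([]), "a")
    with pytest.raises(ValueError, match="multiple orthogroups"):
        validate_ortholog_table(
            _table([("a1", "OG1", "b1"), ("a1", "OG2", "b2")]))
    with pytest.raises(ValueError, match="species"):
        map_orthologs(["a1"], _table([("a1", "OG1", "b1")]), "c")


def test_venn_partition_example():
    part = venn_partition({1, 2, 3}, {2, 3, 4}, set(range(10)))
    assert part.shared == {2, 3}
    assert part.unique_a == {1}
    assert part.unique_b == {4}
    sizes = part.sizes()
    assert sizes["shared"] + sizes["unique_a"] + sizes["unique_b"] == 4


def test_venn_partition_identical_sets():
    part = venn_partition({1, 2}, {1, 2}, {1, 2, 3})
    assert part.unique_a == part.unique_b == frozenset()
    assert part.shared == {1, 2}


def test_venn_partition_outside_background_rejected():
    with pytest.raises(ValueError, match="outside"):
        venn_partition({1, 99}, {2}, {1, 2, 3})


def test_venn_partition_reports_study_scale_sizes():
    """Set arithmetic at the scale of a two-coral DEO comparison:
    199- and 244-element sets overlapping in 73 give 126 and 171
    unique orthogroups."""
    shared = {f"OG{i}" for i in range(73)}
    a = shared | {f"A{i}" for i in range(126)}
    b = shared | {f"B{i}" for i in range(171)}
    background = a | b | {f"X{i}" for i in range(500)}
    part = venn_partition(a, b, background)
    assert part.sizes()["shared"] == 73
    assert part.sizes()["unique_a"] == 126
    assert part.sizes()["unique_b"] == 171


@settings(derandomize=True, max_examples=50)
@given(st.sets(st.integers(0, 40)), st.sets(st.integers(0, 40)))
def test_venn_sizes_sum_to_union(a, b):
    part = venn_partition(a, b, set(range(41)))
    total = sum(part.sizes()[k] for k in ("shared", "unique_a", "unique_b"))
    assert total == len(a | b)


def test_fisher_matches_enumeration_oracle():
    _, p = scipy.stats.fisher_exact([[3, 7], [10, 80]])
    assert p == pytest.approx(fisher_two_sided_oracle(3, 7, 10, 80),
                              abs=1e-12)


def test_fisher_swap_invariance():
    for a, b, c, d in [(3, 7, 10, 80), (0, 5, 9, 2), (4, 4, 4, 4)]:
        _, p = scipy.stats.fisher_exact([[a, b], [c, d]])
        _, p_rows = scipy.stats.fisher_exact([[c, d], [a, b]])
        _, p_cols = scipy.stats.fisher_exact([[b, a], [d, c]])
        assert p == pytest.approx(p_rows, rel=1e-12)
        assert p == pytest.approx(p_cols, rel=1e-12)


def test_fisher_oracle_small_sweep():
    """Exhaustive agreement with the exact-integer oracle on all 2x2
    tables with grand total <= 12."""
    for a, b, c, d in enumerate_small_tables(12):
        _, p = scipy.stats.fisher_exact([[a, b], [c, d]])
        assert abs(p - fisher_two_sided_oracle(a, b, c, d)) < 1e-12


def _term_map(terms: dict):
    rows = [{"element": e, "term": t} for t, els in terms.items() for e in els]
    return pd.DataFrame(rows)


def test_fisher_enrichment_direction_sanity():
    background = [f"OG{i}" for i in range(100)]
    group = set(background[:20])
    tm = _term_map({
        "absent": background[50:60],   # disjoint from the group
        "hit": background[:10],        # fully inside the group
    })
    res = fisher_enrichment(group, background, tm).set_index("term")
    assert res.loc["absent", "odds_ratio"] < 1
    assert res.loc["absent", "p"] > 0.1
    assert res.loc["hit", "odds_ratio"] > 1
    assert res.loc["hit", "p"] < 1e-4


def test_fisher_enrichment_filters_and_errors():
    background = [f"OG{i}" for i in range(30)]
    tm = _term_map({"tiny": background[:2], "ok": background[:8]})
    res = fisher_enrichment(set(background[:5]), background, tm)
    assert set(res["term"]) == {"ok"}
    with pytest.raises(ValueError, match="background"):
        fisher_enrichment({"OGx"}, set(), tm)
    with pytest.raises(ValueError, match="subset"):
        fisher_enrichment({"not_in_bg"}, background, tm)


def test_fisher_null_calibrated():
    from symcell.validation import fisher_null_rate

    rate = fisher_null_rate(seed=1)
    assert rate <= 0.08  # discrete test: at or below nominal
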