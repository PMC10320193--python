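"""Round-trip IO, validation errors and the ortholog-transfer hit filter."""

import numpy as np
import pandas as pd
import pytest

from subbias.data_io import (
    CountMatrix,
    OrthologMap,
    ParseError,
    filter_ortholog_hits,
    read_counts,
    read_hits,
    read_ortholog_map,
    read_samples,
    write_counts,
    write_ortholog_map,
    write_samples,
    HIT_COLUMNS,
)
from subbias.synthetic_data import SimulationConfig, simulate_dataset


# ---------------------------------------------------------------------------
# TSV round trips


def test_count_round_trip_small(tmp_path):
    df = pd.DataFrame(
        [[1, 2], [3, 0], [10, 7]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["s1", "s2"],
    )
    cm = CountMatrix(df, "2n")
    write_counts(cm, tmp_path / "c.tsv")
    back = read_counts(tmp_path / "c.tsv", "2n")
    pd.testing.assert_frame_equal(back.df, df)
    assert back.compartment == "2n"


def test_count_round_trip_simulated(tmp_path, demo_dataset):
    write_counts(demo_dataset.counts_total, tmp_path / "t.tsv")
    back = read_counts(tmp_path / "t.tsv")
    pd.testing.assert_frame_equal(back.df, demo_dataset.counts_total.df)


def test_negative_count_rejected(tmp_path):
    (tmp_path / "bad.tsv").write_text("gene_id\ts1\ng1\t5\ng2\t-1\n")
    with pytest.raises(ParseError, match="negative count.*g2.*s1"):
        read_counts(tmp_path / "bad.tsv")


def test_duplicate_gene_rejected(tmp_path):
    (tmp_path / "bad.tsv").write_text("gene_id\ts1\ng1\t5\ng1\t2\n")
    with pytest.raises(ParseError, match="duplicate gene"):
        read_counts(tmp_path / "bad.tsv")


def test_non_numeric_count_rejected(tmp_path):
    (tmp_path / "bad.tsv").write_text("gene_id\ts1\ng1\tfive\n")
    with pytest.raises(ParseError, match="non-numeric"):
        read_counts(tmp_path / "bad.tsv")


def test_sample_table_round_trip(tmp_path, demo_dataset):
    write_samples(demo_dataset.samples, tmp_path / "s.tsv")
    back = read_samples(tmp_path / "s.tsv")
    pd.testing.assert_frame_equal(back.df, demo_dataset.samples.df)


def test_sample_table_requires_subgenome_ref_iff_allotriploid():
    df = pd.DataFrame(
        {
            "sample_id": ["a", "b"],
            "population": ["P", "P"],
            "ploidy_class": ["allotriploid", "diploid"],
            "subgenome_ref": [None, None],
        }
    )
    from subbias.data_io import SampleTable

    with pytest.raises(ParseError, match="subgenome_ref"):
        SampleTable(df)


def test_ortholog_map_round_trip(tmp_path, demo_dataset):
    write_ortholog_map(demo_dataset.ortholog_maps, tmp_path / "o.tsv")
    back = read_ortholog_map(tmp_path / "o.tsv")
    assert back.pairs == demo_dataset.ortholog_maps.pairs


def test_ortholog_map_rejects_double_target():
    with pytest.raises(ParseError, match="mapped twice"):
        OrthologMap({"P": {"g1": "t1", "g2": "t1"}})


# ---------------------------------------------------------------------------
# hit filtering


def _hits(rows):
    return pd.DataFrame(rows, columns=list(HIT_COLUMNS))


def test_hit_filter_threshold_examples():
    """85% identity and >95% query coverage, as in the transfer scheme."""
    hits = _hits(
        [
            ("q1", "t1", 90.0, 960, 1000, 1e-50, 500.0),  # kept
            ("q2", "t2", 84.9, 960, 1000, 1e-50, 500.0),  # identity too low
            ("q3", "t3", 90.0, 940, 1000, 1e-50, 500.0),  # coverage too low
        ]
    )
    omap = filter_ortholog_hits(hits, population="P")
    assert omap["P"] == {"q1": "t1"}


def test_hit_filter_coverage_is_strict():
    """Coverage exactly 95% of the query is not 'above 95%'."""
    hits = _hits([("q", "t", 90.0, 950, 1000, 1e-50, 100.0)])
    assert filter_ortholog_hits(hits, population="P")["P"] == {}
    hits2 = _hits([("q", "t", 85.0, 951, 1000, 1e-50, 100.0)])
    assert filter_ortholog_hits(hits2, population="P")["P"] == {"q": "t"}


def test_hit_filter_empty():
    assert filter_ortholog_hits(_hits([]), population="P")["P"] == {}


def test_hit_filter_best_hit_and_injectivity():
    hits = _hits(
        [
            ("q1", "tA", 95.0, 990, 1000, 1e-80, 900.0),
            ("q1", "tB", 95.0, 990, 1000, 1e-80, 800.0),  # lower score
            ("q2", "tA", 95.0, 990, 1000, 1e-80, 850.0),  # loses tA to q1
        ]
    )
    omap = filter_ortholog_hits(hits, population="P")
    assert omap["P"] == {"q1": "tA"}  # q2 dropped, not reassigned


def _brute_force_filter(hits: pd.DataFrame, min_id, min_cov):
    surv = [
        r
        for r in hits.itertuples(index=False)
        if r.percent_identity >= min_id
        and r.alignment_length > min_cov * r.query_length
    ]
    best = {}
    for r in surv:
        cur = best.get(r.query_id)
        if (
            cur is None
            or r.bit_score > cur.bit_score
            or (r.bit_score == cur.bit_score and r.target_id < cur.target_id)
        ):
            best[r.query_id] = r
    chosen = {}
    for q in sorted(best):
        r = best[q]
        cur = chosen.get(r.target_id)
        if cur is None or r.bit_score > cur[0]:
            chosen[r.target_id] = (r.bit_score, q)
    return {q: t for t, (_, q) in chosen.items()}


def test_hit_filter_matches_brute_force(rng):
    """Random hit tables across threshold sweeps equal the enumeration oracle."""
    for trial in range(120):
        n = rng.integers(1, 20)
        hits = _hits(
            [
                (
                    f"q{rng.integers(0, 8)}",
                    f"t{rng.integers(0, 8)}",
                    float(rng.uniform(60, 100)),
                    int(rng.integers(500, 1001)),
                    1000,
                    1e-20,
                    float(np.round(rng.uniform(50, 500), 1)),
                )
                for _ in range(n)
            ]
        )
        min_id = float(rng.choice([70, 80, 85, 90]))
        min_cov = float(rng.choice([0.5, 0.8, 0.95]))
        got = filter_ortholog_hits(hits, min_id, min_cov, population="P")["P"]
        assert got == _brute_force_filter(hits, min_id, min_cov)


def test_hit_filter_survival_monotone_and_output_subset(rng):
    """Raising either threshold never lets an extra hit survive the
    identity/coverage filter, and every output pair comes from an input
    hit.  (Monotonicity applies to hit survival; the later best-hit and
    injectivity resolution can reassign pairs when competitors drop out.)
    """

    def survivors(hits, min_id, min_cov):
        return {
            (r.query_id, r.target_id, r.bit_score)
            for r in hits.itertuples(index=False)
            if r.percent_identity >= min_id
            and r.alignment_length > min_cov * r.query_length
        }

    hits = _hits(
        [
            (
                f"q{i}",
                f"t{rng.integers(0, 10)}",
                float(rng.uniform(70, 100)),
                int(rng.integers(700, 1001)),
                1000,
                1e-30,
                float(rng.uniform(100, 400)),
            )
            for i in range(30)
        ]
    )
    loose = survivors(hits, 80, 0.80)
    assert survivors(hits, 90, 0.80) <= loose
    assert survivors(hits, 80, 0.95) <= loose
    input_pairs = set(zip(hits["query_id"], hits["target_id"]))
    for min_id, min_cov in [(70, 0.5), (85, 0.95), (95, 0.99)]:
        out = filter_ortholog_hits(hits, min_id, min_cov, population="P")["P"]
        assert set(out.items()) <= input_pairs


# ---------------------------------------------------------------------------
# BLAST tabular parsing


def test_read_blast_outfmt7(tmp_path):
    text = (
        "# BLASTN 2.12.0+\n"
        "# Query: g1\n"
        "# Fields: query id, subject id, % identity, alignment length, "
        "query length, evalue, bit score\n"
        "g1\ttig1\t97.2\t980\t1000\t1e-100\t850.1\n"
        "g2\ttig2\t88.0\t990\t1000\t1e-90\t700.0\n"
    )
    (tmp_path / "hits.tsv").write_text(text)
    hits = read_hits(tmp_path / "hits.tsv")
    assert list(hits["query_id"]) == ["g1", "g2"]
    assert hits["bit_score"].tolist() == [850.1, 700.0]


def test_read_hits_requires_query_length(tmp_path):
    text = (
        "# Fields: query id, subject id, % identity, alignment length, "
        "evalue, bit score\n"
        "g1\ttig1\t97.2\t980\t1e-100\t850.1\n"
    )
    (tmp_path / "hits.tsv").write_text(text)
    with pytest.raises(ParseError, match="query_length"):
        read_hits(tmp_path / "hits.tsv")
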