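import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodeid import (
    RSL,
    RSLRecord,
    aggregate_by_lineage,
    apply_tags,
    best_match_per_query,
    compute_qcov,
    compute_summary,
    filter_hits,
    load_check_tags,
    similarity_threshold,
)
from barcodeid.errors import CheckTagError, ParameterError, PipelineInternalError
from barcodeid.match_engine import CheckTag, evaluate_hit

from test_blast_io import make_hit


def tiny_rsl(seq_ids):
    return RSL(records=[
        RSLRecord(seq_id=s, lineage="_".join(s.split("_")[:2]), sequence="ACGT")
        for s in seq_ids
    ])


class TestFormulas:
    @pytest.mark.parametrize(
        "qstart, qend, qlen, expected",
        [
            (1, 100, 100, 100.0),
            (26, 100, 100, 75.0),
            (11, 17, 20, 35.0),
            (1, 74, 100, 74.0),
        ],
    )
    def test_qcov(self, qstart, qend, qlen, expected):
        assert compute_qcov(qstart, qend, qlen) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [(0, 5, 10), (6, 5, 10), (1, 11, 10)])
    def test_qcov_invalid_coordinates(self, bad):
        with pytest.raises(ParameterError):
            compute_qcov(*bad)

    @pytest.mark.parametrize(
        "intersp_div, expected", [(3, 97), (0, 100), (12.5, 87.5)]
    )
    def test_similarity_threshold(self, intersp_div, expected):
        assert similarity_threshold(intersp_div) == expected

    @pytest.mark.parametrize("bad", [-1, 100, 150])
    def test_similarity_threshold_range(self, bad):
        with pytest.raises(ParameterError):
            similarity_threshold(bad)


class TestFilterHits:
    def test_low_coverage_removed(self):
        hit = make_hit(qstart=1, qend=74, qlen=100, aln_len=100, slen=100)
        assert filter_hits([hit]) == []

    def test_coverage_boundary_retained(self):
        hit = make_hit(qstart=26, qend=100, qlen=100, aln_len=100, slen=100)
        [ev] = filter_hits([hit])
        assert ev.qcov == 75.0

    def test_subject_span_boundary_retained(self):
        # 90% of the subject length is exactly the floor, not below it
        hit = make_hit(qstart=1, qend=90, qlen=90, aln_len=90, slen=100)
        assert len(filter_hits([hit])) == 1

    def test_short_alignment_removed(self):
        hit = make_hit(qstart=1, qend=89, qlen=89, aln_len=89, slen=100)
        assert filter_hits([hit]) == []

    def test_empty_input(self):
        assert filter_hits([]) == []

    def test_idempotent_and_order_preserving(self):
        hits = [
            make_hit(qseqid="Q2", qstart=1, qend=500),
            make_hit(qseqid="Q1", qstart=1, qend=400),  # qcov 80
            make_hit(qseqid="Q3", qstart=1, qend=100),  # qcov 20, dropped
        ]
        retained = filter_hits(hits)
        assert [ev.hit.qseqid for ev in retained] == ["Q2", "Q1"]
        assert filter_hits([ev.hit for ev in retained]) == retained

    def test_qcov_agrees_with_aligner_qcovs_single_hsp(self):
        """On single-HSP hits the computed coverage tracks the aligner's
        per-subject qcovs column to well under half a point."""
        hit = make_hit(qstart=26, qend=100, qlen=100, qcovs=75.0)
        assert abs(evaluate_hit(hit).qcov - hit.qcovs) < 0.5


def brute_force_best(hits):
    """Independent oracle: per query, scan all retained hits for max pident
    with ties on bitscore desc, aln_len desc, sseqid asc."""
    best = {}
    for ev in filter_hits(hits):
        h = ev.hit
        key = (-h.pident, -h.bitscore, -h.aln_len, h.sseqid)
        if h.qseqid not in best or key < best[h.qseqid][0]:
            best[h.qseqid] = (key, h)
    return {q: h for q, (_, h) in best.items()}


class TestBestMatch:
    def test_max_pident_wins(self):
        rsl = tiny_rsl(["A_b_1", "C_d_1"])
        hits = [
            make_hit(qseqid="Q1", sseqid="A_b_1", pident=99.1),
            make_hit(qseqid="Q1", sseqid="C_d_1", pident=96.0),
        ]
        [m] = best_match_per_query(filter_hits(hits), rsl, threshold=97.0)
        assert (m.sseqid, m.lineage, m.check_identity) == ("A_b_1", "A_b", False)

    def test_below_threshold_flagged(self):
        rsl = tiny_rsl(["A_b_1"])
        hits = [make_hit(qseqid="Q1", sseqid="A_b_1", pident=95.0)]
        [m] = best_match_per_query(filter_hits(hits), rsl, threshold=97.0)
        assert m.check_identity and m.flagged

    def test_tie_breaks_on_bitscore(self):
        rsl = tiny_rsl(["A_b_1", "C_d_1"])
        hits = [
            make_hit(qseqid="Q1", sseqid="C_d_1", pident=99.0, bitscore=900.0),
            make_hit(qseqid="Q1", sseqid="A_b_1", pident=99.0, bitscore=910.0),
        ]
        [m] = best_match_per_query(filter_hits(hits), rsl, threshold=97.0)
        assert m.sseqid == "A_b_1"

    def test_unknown_subject_noted(self):
        rsl = tiny_rsl(["A_b_1"])
        hits = [make_hit(qseqid="Q1", sseqid="Zz_1", pident=99.0)]
        [m] = best_match_per_query(filter_hits(hits), rsl, threshold=97.0)
        assert m.lineage == "Zz_1" and m.notes

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_random_tables(self, seed):
        """Best-match selection agrees with a brute-force scan on random
        hit tables."""
        rng = np.random.default_rng(seed)
        rsl = tiny_rsl([f"G{i}_s{i}_V{i}" for i in range(5)])
        hits = []
        for _ in range(rng.integers(0, 40)):
            qlen = int(rng.integers(50, 400))
            qstart = int(rng.integers(1, qlen + 1))
            qend = int(rng.integers(qstart, qlen + 1))
            slen = int(rng.integers(50, 400))
            hits.append(make_hit(
                qseqid=f"Q{rng.integers(0, 6)}",
                sseqid=f"G{rng.integers(0, 5)}_s0_V0",
                pident=float(rng.integers(80000, 100001)) / 1000.0,
                aln_len=int(rng.integers(1, qlen + 1)),
                qstart=qstart, qend=qend, qlen=qlen,
                sstart=1, send=slen, slen=slen,
                bitscore=float(rng.integers(0, 1000)),
            ))
        expected = brute_force_best(hits)
        got = {m.qseqid: m for m in
               best_match_per_query(filter_hits(hits), rsl, threshold=97.0)}
        assert set(got) == set(expected)
        for q, h in expected.items():
            assert (got[q].sseqid, got[q].pident) == (h.sseqid, h.pident)

    @given(st.lists(st.floats(min_value=0, max_value=99.9), min_size=1,
                    max_size=6, unique=True))
    @settings(max_examples=40, deadline=None)
    def test_flag_count_monotone_in_divergence(self, divergences):
        """Lowering the similarity threshold (raising intersp_div) never
        flags more matches."""
        rsl = tiny_rsl([f"G{i}_s{i}_V{i}" for i in range(8)])
        hits = [
            make_hit(qseqid=f"Q{i}", sseqid=f"G{i}_s{i}_V{i}",
                     pident=90.0 + i * 1.25)
            for i in range(8)
        ]
        counts = []
        for d in sorted(divergences):
            matches = best_match_per_query(
                filter_hits(hits), rsl, threshold=similarity_threshold(d))
            counts.append(sum(m.check_identity for m in matches))
        assert counts == sorted(counts, reverse=True)


class TestCheckTags:
    def test_load_and_apply(self, tmp_path):
        path = tmp_path / "Check_tags.csv"
        path.write_text("Mantella,genus-level id only\nMRSN,check voucher\n")
        tags = load_check_tags(path)
        assert len(tags) == 2
        rsl = tiny_rsl(["Mantella_aurantiaca_MRSN1234"])
        hits = [make_hit(qseqid="Q1", sseqid="Mantella_aurantiaca_MRSN1234")]
        matches = best_match_per_query(filter_hits(hits), rsl, 97.0)
        [m] = apply_tags(matches, tags)
        assert m.notes == ["genus-level id only", "check voucher"]
        assert m.flagged

    def test_header_row_detected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("pattern,message\nMRSN,check voucher\n")
        assert len(load_check_tags(path)) == 1

    def test_absent_file_is_empty(self, tmp_path):
        assert load_check_tags(tmp_path / "nope.csv") == []
        assert load_check_tags(None) == []

    def test_empty_pattern_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("MRSN,ok\n,oops\n")
        with pytest.raises(CheckTagError, match="row 2"):
            load_check_tags(path)

    def test_case_sensitive_by_default(self):
        rsl = tiny_rsl(["Mantella_aurantiaca_MRSN1234"])
        hits = [make_hit(qseqid="Q1", sseqid="Mantella_aurantiaca_MRSN1234")]
        matches = best_match_per_query(filter_hits(hits), rsl, 97.0)
        tags = [CheckTag(pattern="mantella", message="x")]
        assert apply_tags(matches, tags)[0].notes == []
        assert apply_tags(matches, tags, case_sensitive=False)[0].notes == ["x"]

    def test_no_tags_unchanged(self):
        rsl = tiny_rsl(["A_b_1"])
        matches = best_match_per_query(
            filter_hits([make_hit(qseqid="Q1", sseqid="A_b_1")]), rsl, 97.0)
        assert apply_tags(matches, []) == matches


class TestAggregationAndSummary:
    def make_matches(self, rsl, lineage_idx):
        hits = [
            make_hit(qseqid=f"Q{j}", sseqid=rsl.records[i].seq_id)
            for j, i in enumerate(lineage_idx)
        ]
        return best_match_per_query(filter_hits(hits), rsl, 97.0)

    def test_rollup_partition(self):
        rsl = tiny_rsl([f"G{i}_s{i}_V{i}" for i in range(25)])
        matches = self.make_matches(rsl, [0, 1, 2, 3, 4, 5, 6, 0, 1])
        qids = [m.qseqid for m in matches] + ["OUT1"]
        rollup = aggregate_by_lineage(matches, rsl, qids)
        assert len(rollup.by_lineage) == 25
        assert sum(bool(v) for v in rollup.by_lineage.values()) == 7
        assert rollup.below_cutoff == ["OUT1"]
        listed = [q for v in rollup.by_lineage.values() for q in v]
        assert sorted(listed) == sorted(m.qseqid for m in matches)

    def test_no_queries(self):
        rsl = tiny_rsl(["A_b_1"])
        rollup = aggregate_by_lineage([], rsl, [])
        assert rollup.by_lineage == {"A_b": []}
        assert rollup.below_cutoff == []

    def test_summary_benchmark_counts(self):
        rsl = tiny_rsl([f"G{i}_s{i}_V{i}" for i in range(25)])
        matches = self.make_matches(rsl, [0, 1, 2, 3, 4, 5, 6, 0, 1])
        stats = compute_summary(rsl, matches, ["OUT1"], total_queries=10)
        assert stats.total_lineages == 25
        assert stats.taxonomic_coverage == pytest.approx(28.0)
        assert stats.taxa_without_sample == 18
        assert stats.percent_processed == pytest.approx(100.0)
        assert stats.n_below_cutoff == 1

    def test_summary_zero_matches(self):
        rsl = tiny_rsl(["A_b_1", "C_d_1"])
        stats = compute_summary(rsl, [], [], total_queries=0)
        assert stats.taxonomic_coverage == 0.0

    def test_summary_inconsistency_raises(self):
        rsl = tiny_rsl(["A_b_1"])
        with pytest.raises(PipelineInternalError):
            compute_summary(rsl, [], ["Q1", "Q2"], total_queries=1)
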