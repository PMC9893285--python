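import math
import random

import pytest

from cdpep import (
    Motif,
    coverage_table,
    discover_motifs,
    read_motif_list,
    scan_motifs,
)
from cdpep.motifs import DEFAULT_MOTIFS, first_match, write_motif_list

from conftest import make_dataset, random_peptide


# ---------------------------------------------------------------------------
# Independent brute-force oracle for discovery (naive loops throughout)
# ---------------------------------------------------------------------------

def oracle_discover(pos_seqs, neg_seqs, kmin, kmax, min_positive, max_negative):
    def contains(seq, pat):
        return any(seq[i : i + len(pat)] == pat for i in range(len(seq) - len(pat) + 1))

    def pq_frac(p):
        return sum(c in "PQ" for c in p) / len(p)

    all_pats = set()
    for s in pos_seqs:
        for k in range(kmin, kmax + 1):
            for i in range(len(s) - k + 1):
                all_pats.add(s[i : i + k])
    candidates = []
    for p in sorted(all_pats):
        np_ = sum(contains(s, p) for s in pos_seqs)
        nn = sum(contains(s, p) for s in neg_seqs)
        if np_ >= min_positive and nn <= max_negative:
            candidates.append(p)
    # drop patterns containing another candidate
    kept = [
        p
        for p in candidates
        if not any(q != p and contains(p, q) for q in candidates)
    ]
    # collapse identical positive-coverage classes
    cov = {p: frozenset(i for i, s in enumerate(pos_seqs) if contains(s, p)) for p in kept}
    winners = {}
    for p in kept:
        key = cov[p]
        if key not in winners:
            winners[key] = p
        else:
            q = winners[key]
            if (-pq_frac(p), len(p), p) < (-pq_frac(q), len(q), q):
                winners[key] = p
    out = [
        (p, sum(contains(s, p) for s in pos_seqs), sum(contains(s, p) for s in neg_seqs))
        for p in winners.values()
    ]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


class TestDiscovery:
    def test_worked_three_sequence_example(self):
        pos = make_dataset(["QPFAA", "AQPFA", "QQPFA"], "positive", "p")
        neg = make_dataset(["AAAAA", "LLLLL"], "negative", "n")
        found = discover_motifs(pos, neg, kmin=3, kmax=4, min_positive=2, max_negative=0)
        assert found == [Motif("QPF", 3, 0)]

    def test_identical_sets_yield_nothing(self):
        seqs = ["QPFAAQPQ", "PYPACDEF"]
        pos = make_dataset(seqs, "positive", "p")
        neg = make_dataset(seqs, "negative", "n")
        assert discover_motifs(pos, neg, max_negative=0) == []

    def test_returned_support_is_recheckable(self, small_ds):
        from cdpep import PeptideDataset

        pos = PeptideDataset([r for r in small_ds if r.label == "positive"])
        neg = PeptideDataset([r for r in small_ds if r.label == "negative"])
        min_pos = math.ceil(0.05 * len(pos))
        for m in discover_motifs(pos, neg, min_positive=min_pos):
            n_pos = sum(1 for r in pos if m.pattern in r.sequence)
            n_neg = sum(1 for r in neg if m.pattern in r.sequence)
            assert (n_pos, n_neg) == (m.positive_count, m.negative_count)
            assert n_pos >= min_pos and n_neg == 0

    def test_empty_positive_set_rejected(self):
        from cdpep import PeptideDataset

        with pytest.raises(ValueError):
            discover_motifs(PeptideDataset([]), make_dataset(["AAAAA"], "negative"))

    def test_bad_k_rejected(self):
        pos = make_dataset(["QPFAA"], "positive")
        neg = make_dataset(["AAAAA"], "negative")
        with pytest.raises(ValueError):
            discover_motifs(pos, neg, kmin=0)
        with pytest.raises(ValueError):
            discover_motifs(pos, neg, kmin=5, kmax=3)

    def test_matches_brute_force_on_random_datasets(self):
        rng = random.Random(99)
        for trial in range(15):
            pos_seqs = list(
                {random_peptide(rng, 6, 14, "APQFL") for _ in range(rng.randint(5, 25))}
            )
            neg_seqs = list(
                {random_peptide(rng, 6, 14, "APQFL") for _ in range(rng.randint(5, 25))}
            )
            min_pos = rng.randint(2, 4)
            max_neg = rng.randint(0, 1)
            got = discover_motifs(
                make_dataset(pos_seqs, "positive", "p"),
                make_dataset(neg_seqs, "negative", "n"),
                kmin=3,
                kmax=5,
                min_positive=min_pos,
                max_negative=max_neg,
            )
            want = oracle_discover(pos_seqs, neg_seqs, 3, 5, min_pos, max_neg)
            assert [(m.pattern, m.positive_count, m.negative_count) for m in got] == want


class TestScan:
    def test_worked_example(self):
        hits = scan_motifs("LQLQPFPQPQ", ["QPF", "PQPQ"], "q")
        assert [(h.pattern, h.start) for h in hits] == [("QPF", 4), ("PQPQ", 7)]

    def test_no_hits(self):
        assert scan_motifs("AAAA", ["QPF"]) == []

    def test_overlapping_occurrences_reported(self):
        hits = scan_motifs("QPQPQ", ["QPQ"])
        assert [(h.pattern, h.start) for h in hits] == [("QPQ", 1), ("QPQ", 3)]

    def test_empty_motif_list_rejected(self):
        with pytest.raises(ValueError):
            scan_motifs("AAAA", [])

    def test_matches_naive_search(self):
        rng = random.Random(5)
        motifs = ["QPF", "QPQ", "PQPQ", "PYP"]
        for _ in range(200):
            seq = random_peptide(rng, 9, 30, "APQFY")
            naive = sorted(
                (i + 1, m)
                for m in motifs
                for i in range(len(seq) - len(m) + 1)
                if seq[i : i + len(m)] == m
            )
            got = [(h.start, h.pattern) for h in scan_motifs(seq, motifs)]
            assert got == naive


class TestCoverage:
    def test_hand_counted_example(self):
        pos = make_dataset(["AQPFA", "QPQAA", "LLLLL"], "positive")
        table = coverage_table(["QPF", "QPQ"], pos)
        assert [(r.pattern, r.count, r.percentage, r.cumulative) for r in table.rows] == [
            ("QPF", 1, 33.33, 33.33),
            ("QPQ", 1, 33.33, 66.67),
        ]
        assert table.residual_count == 1
        assert table.residual_percentage == 33.33

    def test_full_coverage_has_zero_residual(self):
        pos = make_dataset(["AQPFA", "QPQAA"], "positive")
        table = coverage_table(["QPF", "QPQ"], pos)
        assert table.residual_count == 0
        assert table.rows[-1].cumulative == pytest.approx(100.0, abs=0.01)

    def test_first_match_attribution(self):
        # contains both QPF and QPQ; attributed to the earlier-listed motif only
        pos = make_dataset(["QPFQPQAA"], "positive")
        table = coverage_table(["QPF", "QPQ"], pos)
        assert table.rows[0].count == 1
        assert table.rows[1].count == 0
        assert first_match("QPFQPQAA", ["QPQ", "QPF"]) == "QPQ"

    def test_cumulative_monotone_and_bounded(self, small_ds):
        from cdpep import PeptideDataset

        pos = PeptideDataset([r for r in small_ds if r.label == "positive"])
        table = coverage_table(list(DEFAULT_MOTIFS), pos)
        cums = [r.cumulative for r in table.rows]
        assert cums == sorted(cums)
        assert cums[-1] <= 100.0 + 1e-9
        assert cums[-1] + table.residual_percentage == pytest.approx(100.0, abs=0.02)
        assert sum(r.count for r in table.rows) + table.residual_count == len(pos)


class TestMotifListIO:
    def test_round_trip(self, tmp_path):
        motifs = [Motif("QPF", 276, 4), Motif("QPQ", 350, 0)]
        path = tmp_path / "motifs.tsv"
        write_motif_list(motifs, path)
        assert read_motif_list(path) == motifs

    def test_bare_patterns_and_comments(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("# curated\nqpf\n\nPYP\n")
        assert [m.pattern for m in read_motif_list(path)] == ["QPF", "PYP"]
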