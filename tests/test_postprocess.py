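"""Phase-4 tests: dropped-allele promotion, chimera screening, length
screen, diagnostics and output assembly."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from stclust import (
    AlleleOrigin,
    Cluster,
    ClusterSet,
    ClusterStatus,
    Genotype,
    assemble_outputs,
    classify_chimeras,
    diagnostics,
    find_recombinant_candidates,
    length_screen,
    promote_dropped,
)

A = "A" * 213
B = "C" * 213
C = "G" * 213
RARE = "T" * 213


def _cset(sample_id, good_counts, small_counts, library_size=330):
    def mk(seq, n, status):
        c = Cluster({seq: n}, 97.0)
        c.status = status
        return c

    return ClusterSet(
        sample_id,
        [mk(s, n, ClusterStatus.GOOD) for s, n in good_counts.items()],
        [mk(s, n, ClusterStatus.SMALL) for s, n in small_counts.items()],
        [],
        library_size,
    )


class TestPromotion:
    def _clustersets(self, n_other=3, rare_reads=4):
        csets = {"X": _cset("X", {A: 100, B: 50}, {RARE: rare_reads, C: 3})}
        for i in range(n_other):
            sid = f"S{i}"
            csets[sid] = _cset(sid, {A: 80, RARE: 40}, {})
        return csets

    def test_small_cluster_promoted_when_common(self):
        genotypes, catalog = promote_dropped(self._clustersets(), epsilon=3)
        gx = next(g for g in genotypes if g.sample_id == "X")
        assert (RARE, AlleleOrigin.DROPPED, 4) in gx.alleles
        # C labels no good cluster anywhere: stays an artifact
        assert C not in gx.allele_seqs
        row = catalog[catalog.allele == RARE].iloc[0]
        assert row.n_samples_dropped == 1 and row.n_samples_good == 3

    def test_min_reads_gate(self):
        # a 1-read small cluster matching a common allele is still not
        # promoted (clusters need at least 3 reads in total)
        genotypes, _ = promote_dropped(
            self._clustersets(rare_reads=1), epsilon=3, min_dropped_reads=3
        )
        gx = next(g for g in genotypes if g.sample_id == "X")
        assert RARE not in gx.allele_seqs

    def test_epsilon_counts_other_samples_only(self):
        # good clusters in only 2 other samples: epsilon=3 fails
        genotypes, _ = promote_dropped(self._clustersets(n_other=2), epsilon=3)
        gx = next(g for g in genotypes if g.sample_id == "X")
        assert RARE not in gx.allele_seqs

    def test_epsilon_monotonicity(self):
        counts = []
        for eps in (1, 2, 3, 4, 5):
            genotypes, _ = promote_dropped(self._clustersets(), epsilon=eps)
            counts.append(sum(len(g.alleles) for g in genotypes))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_promotion_never_removes_good_alleles(self):
        csets = self._clustersets()
        genotypes, _ = promote_dropped(csets, epsilon=3)
        for g in genotypes:
            good_labels = {c.label for c in csets[g.sample_id].good}
            assert good_labels <= set(g.allele_seqs)


class TestRecombinants:
    def test_single_crossover_found(self):
        a, b = "AAAAAA", "TTTTTT"
        d = "AAATTT"
        hits = find_recombinant_candidates([a, b, d])
        assert any(h[0] == d and {h[1], h[2]} == {a, b} for h in hits)
        bp = next(h[3] for h in hits if h[0] == d and h[1] == a)
        assert 1 <= bp <= 3

    def test_daughter_must_differ_from_parents(self):
        hits = find_recombinant_candidates(["AAAAAA", "TTTTTT", "AAAAAA"])
        assert not any(h[0] == "AAAAAA" for h in hits)

    def test_unrelated_triple_is_clean(self, rng):
        """Random alleles with no crossover structure yield nothing;
        brute force over all breakpoints confirms the absence."""
        alleles = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(3)]
        assert find_recombinant_candidates(alleles) == []
        for d, a, b in itertools.permutations(alleles, 3):
            for k in range(1, len(d)):
                assert not (d[:k] == a[:k] and d[k:] == b[k:])


class TestChimeras:
    def _genotypes(self, chimera_samples, clean_samples=0):
        a, b = "AAAATTTTGGGG", "CCCCGGGGTTTT"
        d = a[:6] + b[6:]
        genos = []
        for i in range(chimera_samples):
            genos.append(
                Genotype(f"c{i}", [(a, AlleleOrigin.GOOD, 50),
                                   (b, AlleleOrigin.GOOD, 40),
                                   (d, AlleleOrigin.GOOD, 10)])
            )
        for i in range(clean_samples):
            # the daughter occurs without its parents
            genos.append(
                Genotype(f"n{i}", [(d, AlleleOrigin.GOOD, 30),
                                   ("GGGGAAAACCCC", AlleleOrigin.GOOD, 20)])
            )
        return genos, d

    def test_always_with_parents_is_chimera(self):
        genos, d = self._genotypes(4)
        pruned, report = classify_chimeras(genos)
        row = report[report.allele == d].iloc[0]
        assert row.percent_with_parents == 100.0 and bool(row.is_chimera)
        assert all(d not in g.allele_seqs for g in pruned)

    def test_partial_cooccurrence_is_not_chimera(self):
        genos, d = self._genotypes(4, clean_samples=10)
        pruned, report = classify_chimeras(genos)
        row = report[report.allele == d].iloc[0]
        assert row.n_occurrences == 14 and row.n_occurrences_with_parents == 4
        assert row.percent_with_parents == pytest.approx(100 * 4 / 14)
        assert not bool(row.is_chimera)
        assert any(d in g.allele_seqs for g in pruned)

    def test_no_parent_pair_anywhere_not_evaluated(self):
        genos = [
            Genotype("x", [("AAAAAAAA", AlleleOrigin.GOOD, 10),
                           ("CCCCCCCC", AlleleOrigin.GOOD, 10),
                           ("GGGGGGGG", AlleleOrigin.GOOD, 10)])
        ]
        pruned, report = classify_chimeras(genos)
        assert report.empty
        assert pruned[0].allele_seqs == genos[0].allele_seqs

    def test_order_independence(self):
        genos, d = self._genotypes(3, clean_samples=2)
        _, fwd = classify_chimeras(genos)
        _, rev = classify_chimeras(list(reversed(genos)))
        assert fwd.sort_values("allele", ignore_index=True).equals(
            rev.sort_values("allele", ignore_index=True)
        )


def test_length_screen():
    genos = [
        Genotype("x", [(A, AlleleOrigin.GOOD, 50), ("C" * 212, AlleleOrigin.GOOD, 20)])
    ]
    screened, removed = length_screen(genos, expected_len=213, enabled=True)
    assert screened[0].allele_seqs == [A]
    assert removed == [("x", "C" * 212)]
    untouched, removed_off = length_screen(genos, 213, enabled=False)
    assert untouched[0].allele_seqs == genos[0].allele_seqs and not removed_off


class TestDiagnostics:
    def _run(self):
        csets, genos = {}, []
        sizes = [200, 300, 400, 500]
        for i, size in enumerate(sizes):
            sid = f"s{i}"
            csets[sid] = _cset(sid, {A: size // 2, B: size // 4}, {}, size)
            alleles = [(A, AlleleOrigin.GOOD, size // 2),
                       (B, AlleleOrigin.GOOD, size // 4)]
            if i >= 1:
                alleles.append((RARE, AlleleOrigin.DROPPED if i == 1 else AlleleOrigin.GOOD, 10 * i))
            genos.append(Genotype(sid, alleles))
        return genos, csets

    def test_catalog_and_drop_rates(self):
        genos, csets = self._run()
        out = diagnostics(genos, csets)
        cat = out["allele_catalog"].set_index("allele")
        assert cat.loc[A, "drop_rate"] == 0.0
        assert cat.loc[RARE, "n_samples_total"] == 3
        assert cat.loc[RARE, "drop_rate"] == pytest.approx(1 / 3)

    def test_library_size_correlation(self):
        genos, csets = self._run()
        out = diagnostics(genos, csets, min_library_sweep=[250])
        r, p = out["library_size_vs_allele_count"]
        assert r > 0  # larger libraries hold more alleles here
        assert 250 in out["library_size_sweep"]

    def test_degenerate_correlations_absent(self):
        csets = {f"s{i}": _cset(f"s{i}", {A: 100}, {}, 200) for i in range(3)}
        genos = [Genotype(f"s{i}", [(A, AlleleOrigin.GOOD, 100)]) for i in range(3)]
        out = diagnostics(genos, csets)
        assert out["library_size_vs_allele_count"] is None  # zero variance
        assert out["drop_rate_vs_cluster_size"] is None  # nothing dropped


def test_assemble_outputs():
    genos = [
        Genotype("s1", [(A, AlleleOrigin.GOOD, 50), (B, AlleleOrigin.GOOD, 20)]),
        Genotype("s2", [(A, AlleleOrigin.GOOD, 70), (C, AlleleOrigin.DROPPED, 5)]),
    ]
    matrix, ids = assemble_outputs(genos)
    assert matrix.shape == (2, 3)
    id_of = {seq: aid for aid, seq in ids}
    assert ids[0][1] == A  # most frequent allele first
    assert matrix.loc["s1", id_of[A]] == 1 and matrix.loc["s1", id_of[C]] == 0
    assert matrix.sum(axis=1).tolist() == [2, 2]

    empty_matrix, empty_ids = assemble_outputs([])
    assert empty_matrix.empty and not empty_ids
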