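"""Sketching, Mash similarity, fragment ANI/ASI and homolog filtering."""

import math

import numpy as np
import pytest

from modpolisher._seq import revcomp
from modpolisher.sketch import (GenomeSketch, build_sketch, mash_similarity,
                                rank_candidates, fragment_ani, filter_homologs,
                                SimilarityRecord, save_sketch_db, load_sketch_db)

from conftest import random_genome, mutate


def brute_canonical_kmers(seq: str, k: int) -> set[str]:
    """Independent string-based oracle for the canonical k-mer set."""
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if set(kmer) <= set("ACGT"):
            out.add(min(kmer, revcomp(kmer)))
    return out


def brute_mash(seq_a: str, seq_b: str, k: int) -> tuple[float, float]:
    """Jaccard over complete canonical k-mer sets, pushed through the Mash formula."""
    a, b = brute_canonical_kmers(seq_a, k), brute_canonical_kmers(seq_b, k)
    j = len(a & b) / len(a | b)
    if j == 0:
        return 0.0, 0.0
    d = -(1 / k) * math.log(2 * j / (1 + j))
    return j, max(0.0, min(1.0, 1 - d))


class TestBuildSketch:
    def test_deterministic(self, rng):
        g = random_genome(rng, 2000)
        a = build_sketch(g, 21, 1000)
        b = build_sketch(g, 21, 1000)
        assert np.array_equal(a.hashes, b.hashes)

    def test_strand_symmetric(self, rng):
        g = random_genome(rng, 2000)
        a = build_sketch(g, 21, 1000)
        b = build_sketch(revcomp(g), 21, 1000)
        assert np.array_equal(a.hashes, b.hashes)

    def test_enumerated_canonical_kmers(self):
        # 4-mers of ACGTACGT: ACGT, CGTA, GTAC, TACG, ACGT; canonically
        # TACG -> CGTA and ACGT is its own reverse complement, so the
        # distinct canonical set is {ACGT, CGTA, GTAC}.
        sk = build_sketch("ACGTACGT", k=4, sketch_size=1000)
        assert len(sk.hashes) == 3
        singles = {build_sketch(kmer, 4, 10).hashes[0]
                   for kmer in ("ACGT", "CGTA", "GTAC")}
        assert singles == set(sk.hashes.tolist())

    def test_n_kmers_skipped(self):
        sk = build_sketch("ACGTNACGT", k=4, sketch_size=100)
        # only the two flanking ACGT windows are N-free, both canonical ACGT
        assert len(sk.hashes) == 1

    def test_errors(self):
        with pytest.raises(ValueError):
            build_sketch("ACG", k=4)
        with pytest.raises(ValueError):
            build_sketch("ACGTACGT", k=1)
        with pytest.raises(ValueError):
            GenomeSketch("x", 21, 2, hashes=np.array([5, 3], dtype=np.uint64),
                         genome_length=100)


class TestMashSimilarity:
    def test_identical_and_disjoint(self, rng):
        g = random_genome(rng, 3000)
        a = build_sketch(g, 21, 500)
        assert mash_similarity(a, a) == (1.0, 1.0)
        b = build_sketch(random_genome(rng, 3000), 21, 500)
        poly_a = build_sketch("A" * 100, 21, 500)
        poly_c = build_sketch("C" * 100, 21, 500)
        assert mash_similarity(poly_a, poly_c) == (0.0, 0.0)
        assert b.k == 21  # sanity

    def test_symmetry(self, rng):
        g = random_genome(rng, 5000)
        h = mutate(g, rng, 50)
        a, b = build_sketch(g, 21, 300), build_sketch(h, 21, 300)
        assert mash_similarity(a, b) == mash_similarity(b, a)

    def test_full_sketch_equals_brute_force(self, rng):
        """With sketches holding every k-mer, the estimator is exact."""
        g = random_genome(rng, 2000)
        h = mutate(g, rng, 20)
        s = 10_000  # > |union of canonical k-mer sets|
        a, b = build_sketch(g, 21, s), build_sketch(h, 21, s)
        jac, ident = mash_similarity(a, b)
        bj, bi = brute_mash(g, h, 21)
        assert jac == pytest.approx(bj, abs=1e-12)
        assert ident == pytest.approx(bi, abs=1e-12)

    def test_sampled_sketch_close_to_brute_force(self, rng):
        g = random_genome(rng, 10_000)
        h = mutate(g, rng, 100)  # 1% point mutations
        a, b = build_sketch(g, 21, 1000), build_sketch(h, 21, 1000)
        _, ident = mash_similarity(a, b)
        _, brute_ident = brute_mash(g, h, 21)
        assert ident == pytest.approx(brute_ident, abs=0.01)

    def test_k_mismatch_rejected(self, rng):
        g = random_genome(rng, 1000)
        with pytest.raises(ValueError):
            mash_similarity(build_sketch(g, 21, 100), build_sketch(g, 15, 100))


class TestRankCandidates:
    def _db(self, rng, n=5, length=3000):
        g = random_genome(rng, length)
        db = [build_sketch(mutate(g, rng, 10), 21, 500, genome_id=f"g{i}")
              for i in range(n)]
        return g, db

    def test_self_ranked_first(self, rng):
        g, db = self._db(rng)
        db.append(build_sketch(g, 21, 500, genome_id="self"))
        draft = build_sketch(g, 21, 500, genome_id="draft")
        records = rank_candidates(draft, db)
        assert records[0].genome_id == "self"
        assert records[0].mash_identity == 1.0

    def test_identity_cutoff_is_strict(self, rng):
        g = random_genome(rng, 3000)
        far = build_sketch(random_genome(rng, 3000), 21, 500, genome_id="far")
        draft = build_sketch(g, 21, 500)
        assert rank_candidates(draft, [far], min_identity=0.95) == []

    def test_top_t_truncation(self, rng):
        g, _ = self._db(rng, n=0)
        db = [build_sketch(mutate(g, rng, 5), 21, 500, genome_id=f"g{i:02d}")
              for i in range(25)]
        draft = build_sketch(g, 21, 500)
        records = rank_candidates(draft, db, t=20)
        assert len(records) == 20
        idents = [r.mash_identity for r in records]
        assert idents == sorted(idents, reverse=True)

    def test_ties_broken_lexicographically(self, rng):
        g = random_genome(rng, 3000)
        draft = build_sketch(g, 21, 500)
        db = [build_sketch(g, 21, 500, genome_id=name) for name in ("b", "a", "c")]
        records = rank_candidates(draft, db)
        assert [r.genome_id for r in records] == ["a", "b", "c"]

    def test_empty_database(self, rng):
        draft = build_sketch(random_genome(rng, 1000), 21, 100)
        assert rank_candidates(draft, []) == []


class TestFragmentAni:
    def test_self_alignment(self, rng):
        q = random_genome(rng, 9000)
        assert fragment_ani(q, q, 3000) == (100.0, 100.0)

    def test_half_replaced_reference(self, rng):
        """Fragments wholly inside the destroyed half stop aligning."""
        q = random_genome(rng, 12_000)
        ref = q[:6000] + random_genome(rng, 6000)
        ani, asi = fragment_ani(q, ref, 3000)
        assert asi == pytest.approx(50.0, abs=2.0)
        assert ani == pytest.approx(100.0, abs=0.5)

    @pytest.mark.parametrize("rate", [0.0, 0.005, 0.01])
    def test_substitution_rate_recovery(self, rng, rate):
        q = random_genome(rng, 30_000)
        ref = mutate(q, rng, int(rate * len(q)))
        ani, asi = fragment_ani(q, ref, 3000)
        assert asi == 100.0
        assert ani == pytest.approx(100.0 * (1 - rate), abs=0.2)

    def test_asi_monotone_in_destroyed_blocks(self, rng):
        q = random_genome(rng, 15_000)
        asis = []
        ref = q
        for destroyed in range(0, 5):
            ref = (q[:len(q) - destroyed * 3000]
                   + random_genome(rng, destroyed * 3000))
            asis.append(fragment_ani(q, ref, 3000)[1])
        assert all(a >= b for a, b in zip(asis, asis[1:]))

    def test_terminal_remainder_rule(self, rng):
        q = random_genome(rng, 3000 + 1400)  # remainder < 1500 dropped
        ani, asi = fragment_ani(q, q, 3000)
        assert (ani, asi) == (100.0, 100.0)
        with pytest.raises(ValueError):
            fragment_ani(random_genome(rng, 1000), q, 3000)

    def test_nothing_aligns(self, rng):
        q = random_genome(rng, 3000)
        ani, asi = fragment_ani(q, random_genome(rng, 3000), 3000)
        assert ani is None
        assert asi == 0.0


class TestFilterHomologs:
    def _rec(self, gid, ani, asi):
        return SimilarityRecord(genome_id=gid, mash_jaccard=0.9,
                                mash_identity=0.99, ani=ani, asi=asi)

    def test_strict_pass(self):
        recs = [self._rec(f"g{i}", 99.5, 95.0) for i in range(5)]
        out = filter_homologs(recs)
        assert len(out) == 5
        assert all(r.retained and not r.fallback_used for r in out)

    def test_fallback_when_too_few_survive(self):
        recs = ([self._rec("good0", 99.5, 95.0), self._rec("good1", 99.5, 95.0)]
                + [self._rec(f"bad{i}", 98.0, 95.0) for i in range(8)])
        out = filter_homologs(recs)
        assert len(out) == 10
        assert all(r.fallback_used and r.retained for r in out)

    def test_boundary_is_strict(self):
        recs = [self._rec("edge", 99.0, 95.0)] + \
            [self._rec(f"g{i}", 99.5, 95.0) for i in range(3)]
        out = filter_homologs(recs)
        assert "edge" not in {r.genome_id for r in out}
        recs2 = [self._rec("edge_asi", 99.5, 90.0)] + \
            [self._rec(f"g{i}", 99.5, 95.0) for i in range(3)]
        assert "edge_asi" not in {r.genome_id for r in filter_homologs(recs2)}

    def test_undefined_ani_fails_strict(self):
        recs = [self._rec("noali", None, 0.0)] + \
            [self._rec(f"g{i}", 99.5, 95.0) for i in range(3)]
        assert "noali" not in {r.genome_id for r in filter_homologs(recs)}

    def test_subset_or_all_never_mixed(self):
        recs = [self._rec(f"g{i}", 99.5 if i % 2 else 98.0, 95.0)
                for i in range(8)]
        out = filter_homologs(recs)
        ids_in = [r.genome_id for r in recs]
        ids_out = [r.genome_id for r in out]
        assert set(ids_out) <= set(ids_in)
        assert all(r.fallback_used for r in out) or \
            all(not r.fallback_used for r in out)

    def test_empty(self):
        assert filter_homologs([]) == []


class TestSketchDatabase:
    def test_round_trip(self, rng, tmp_path):
        sketches = [build_sketch(random_genome(rng, 2000), 21, 200,
                                 genome_id=f"g{i}") for i in range(3)]
        path = tmp_path / "db.tsv"
        save_sketch_db(path, sketches)
        loaded = load_sketch_db(path)
        assert [s.genome_id for s in loaded] == [s.genome_id for s in sketches]
        for a, b in zip(sketches, loaded):
            assert np.array_equal(a.hashes, b.hashes)
            assert (a.k, a.sketch_size, a.hash_seed,
                    a.genome_length) == (b.k, b.sketch_size, b.hash_seed,
                                         b.genome_length)

    def test_rejects_garbage(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("not a database\n")
        with pytest.raises(ValueError):
            load_sketch_db(p)
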