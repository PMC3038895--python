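"""Membership scoring, argmax assignment, quality thresholding."""

import math

import numpy as np
import pytest

from raibin.classifier import (
    Assignment,
    UnclassifiableFragment,
    apply_quality_threshold,
    classify,
    classify_all,
    fragment_kmer_frequencies,
    membership_score,
)
from raibin.io_formats import Fragment, Lineage, ProfileDatabase
from raibin.kmer_stats import kmer_index
from raibin.rai_core import RAIProfile, build_profile
from raibin.synthetic import random_source, simulate_genome

from conftest import random_dna


def make_profile(ref_id, k, scores):
    return RAIProfile(ref_id=ref_id, k=k, scores=np.asarray(scores, dtype=float))


def make_db(profiles):
    return ProfileDatabase(
        k=profiles[0].k,
        profiles=profiles,
        lineages={p.ref_id: Lineage(species=p.ref_id) for p in profiles},
    )


def brute_force_membership(seq, profile):
    """Oracle: walk every window position, sum scores, divide by window count."""
    k, total, n = profile.k, 0.0, 0
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) <= set("ACGT"):
            total += profile.scores[kmer_index(w)]
            n += 1
    return total / n


class TestMembershipScore:
    def test_single_kmer_fragment(self):
        scores = np.zeros(64)
        scores[kmer_index("AAA")] = 2.0
        p = make_profile("x", 3, scores)
        assert membership_score(Fragment("f", "AAAA"), p) == pytest.approx(2.0)

    def test_zero_profile_gives_zero(self, rng):
        p = make_profile("x", 3, np.zeros(64))
        assert membership_score(Fragment("f", random_dna(rng, 200)), p) == 0.0

    def test_matches_per_window_brute_force(self, rng):
        p = make_profile("x", 4, rng.standard_normal(256))
        for _ in range(5):
            seq = random_dna(rng, 300)
            assert membership_score(Fragment("f", seq), p) == pytest.approx(
                brute_force_membership(seq, p), abs=1e-9
            )

    def test_n_windows_excluded(self):
        scores = np.zeros(16)
        scores[kmer_index("AA")] = 1.0
        scores[kmer_index("CC")] = 3.0
        p = make_profile("x", 2, scores)
        # valid windows: AA, CC -> mean = 2.0 ("AN","NC" dropped)
        assert membership_score(Fragment("f", "AANCC"), p) == pytest.approx(2.0)

    def test_too_short_fragment_raises(self):
        p = make_profile("x", 3, np.zeros(64))
        with pytest.raises(UnclassifiableFragment):
            membership_score(Fragment("f", "AC"), p)

    def test_all_n_fragment_raises(self):
        p = make_profile("x", 2, np.zeros(16))
        with pytest.raises(UnclassifiableFragment):
            membership_score(Fragment("f", "NNNNNN"), p)


class TestClassify:
    def test_argmax_invariant_to_frequency_scaling(self, rng):
        # count weighting vs relative-frequency weighting give identical argmax
        profiles = [make_profile(f"g{i}", 3, rng.standard_normal(64)) for i in range(4)]
        db = make_db(profiles)
        for _ in range(10):
            frag = Fragment("f", random_dna(rng, rng.integers(50, 500)))
            freqs = fragment_kmer_frequencies(frag, 3)
            counts = freqs * (len(frag.sequence) - 2)  # un-normalised weighting
            by_freq = max(profiles, key=lambda p: p.scores @ freqs).ref_id
            by_count = max(profiles, key=lambda p: p.scores @ counts).ref_id
            assert classify(frag, db).best_ref_id == by_freq == by_count

    def test_tie_breaks_to_lexicographically_smallest(self):
        same = np.ones(16)
        db = make_db([make_profile("zeta", 2, same), make_profile("alpha", 2, same)])
        a = classify(Fragment("f", "ACGTAC"), db)
        assert a.best_ref_id == "alpha"
        assert a.quality == 0.0

    def test_quality_is_margin_and_nonnegative(self, rng):
        db = make_db([make_profile(f"g{i}", 3, rng.standard_normal(64)) for i in range(3)])
        a = classify(Fragment("f", random_dna(rng, 100)), db)
        assert a.quality == pytest.approx(a.best_score - a.second_score)
        assert a.quality >= 0
        assert a.best_ref_id != a.second_ref_id

    def test_identical_profiles_quality_zero(self, rng):
        scores = rng.standard_normal(64)
        db = make_db([make_profile("a", 3, scores), make_profile("b", 3, scores)])
        assert classify(Fragment("f", random_dna(rng, 80)), db).quality == 0.0

    def test_single_profile_database(self, rng):
        db = make_db([make_profile("only", 3, rng.standard_normal(64))])
        a = classify(Fragment("f", random_dna(rng, 60)), db)
        assert a.best_ref_id == "only"
        assert a.second_ref_id is None
        assert math.isinf(a.quality)
        assert a.classified

    def test_same_source_fragments_prefer_own_profile(self):
        k = 7
        src_a, src_b = random_source(3, seed=21), random_source(3, seed=22)
        genome_a = simulate_genome(src_a, 300_000)
        genome_b = simulate_genome(src_b, 300_000)
        db = make_db(
            [build_profile(genome_a, k, ref_id="A"), build_profile(genome_b, k, ref_id="B")]
        )
        rng = np.random.default_rng(8)
        starts = rng.integers(0, 299_000, size=50)
        wins = sum(
            classify(Fragment("f", genome_a[s : s + 1000]), db).best_ref_id == "A"
            for s in starts
        )
        assert wins >= 48

    def test_classify_all_flags_unclassifiable(self, rng):
        db = make_db([make_profile("g", 3, rng.standard_normal(64))])
        frags = [Fragment("ok", random_dna(rng, 50)), Fragment("short", "AC")]
        out = classify_all(frags, db)
        assert out[0].classified
        assert out[1].unclassifiable and out[1].best_ref_id is None


class TestQualityThreshold:
    def _assignments(self, n, cls="g"):
        return [
            Assignment(
                frag_id=f"{cls}f{i:02d}", best_ref_id=cls, best_score=1.0,
                second_ref_id="h", second_score=0.0, quality=float(i), classified=True,
            )
            for i in range(n)
        ]

    def test_p100_keeps_everything(self):
        out = apply_quality_threshold(self._assignments(5), 100)
        assert all(a.classified for a in out)

    def test_half_of_four_member_class(self):
        out = apply_quality_threshold(self._assignments(4), 50)
        kept = [a.frag_id for a in out if a.classified]
        assert len(kept) == 2
        assert kept == ["gf02", "gf03"]  # the two highest-quality members

    def test_ceil_rule(self):
        out = apply_quality_threshold(self._assignments(5), 50)
        assert sum(a.classified for a in out) == 3  # ceil(2.5)

    def test_decreasing_p_is_monotone_shrinkage(self):
        asn = self._assignments(7) + self._assignments(4, cls="h")
        kept_prev = None
        for p in (100, 75, 50, 25, 10):
            kept = {a.frag_id for a in apply_quality_threshold(asn, p) if a.classified}
            if kept_prev is not None:
                assert kept <= kept_prev
            kept_prev = kept

    def test_classes_thresholded_independently(self):
        asn = self._assignments(4, cls="g") + self._assignments(2, cls="h")
        out = apply_quality_threshold(asn, 50)
        per_class = {}
        for a in out:
            per_class.setdefault(a.best_ref_id, []).append(a.classified)
        assert sum(per_class["g"]) == 2
        assert sum(per_class["h"]) == 1

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            apply_quality_threshold([], 0)
        with pytest.raises(ValueError):
            apply_quality_threshold([], 101)
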