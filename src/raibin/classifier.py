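"""Fragment classification against a profile database.

A fragment's membership score under a profile is the frequency-weighted
sum of the profile's k-mer scores,

    E_F = sum_w f_F(w) * rai(w),

where f_F(w) is the fragment's k-mer relative frequency over its valid
windows (windows containing N do not count).  Normalising by the window
count makes scores comparable across fragment lengths — which is what
lets the refinement loop track an average score — while leaving the
argmax over profiles unchanged relative to raw-count weighting.

The fragment goes to the profile with the highest score; the quality
score q(F) is the margin between the best and second-best scores and is
0 exactly when the fragment fits two models equally well.  Top-p%
thresholding keeps, within each assigned class, the ceil(p% * n) highest
quality fragments and relabels the rest "unknown".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .io_formats import Fragment, ProfileDatabase
from .kmer_stats import encode_sequence
from .rai_core import RAIProfile

__all__ = [
    "Assignment",
    "UnclassifiableFragment",
    "membership_score",
    "classify",
    "classify_all",
    "fragment_kmer_frequencies",
    "apply_quality_threshold",
]


class UnclassifiableFragment(ValueError):
    """Raised when a fragment has no valid window of length k."""


@dataclass(frozen=True)
class Assignment:
    frag_id: str
    best_ref_id: str | None
    best_score: float = math.nan
    second_ref_id: str | None = None
    second_score: float = math.nan
    quality: float = math.nan
    classified: bool = False

    @property
    def unclassifiable(self) -> bool:
        return self.best_ref_id is None


def fragment_kmer_frequencies(fragment: Fragment | str, k: int) -> np.ndarray:
    """Relative k-mer frequencies of a fragment over its valid windows (sums to 1)."""
    seq = fragment if isinstance(fragment, str) else fragment.sequence
    enc = encode_sequence(seq)
    if enc.size < k:
        raise UnclassifiableFragment(f"fragment shorter than k={k}: unclassifiable")
    codes = np.where(enc >= 0, enc, 0).astype(np.int64)
    valid = enc >= 0
    win = codes[: enc.size - k + 1].copy()
    win_valid = valid[: enc.size - k + 1].copy()
    for j in range(1, k):
        win = win * 4 + codes[j : enc.size - k + 1 + j]
        win_valid &= valid[j : enc.size - k + 1 + j]
    sel = win[win_valid]
    if sel.size == 0:
        raise UnclassifiableFragment("fragment has no N-free window of length k: unclassifiable")
    counts = np.bincount(sel, minlength=4**k)
    return counts / sel.size


def membership_score(fragment: Fragment | str, profile: RAIProfile) -> float:
    """E_F for one fragment against one profile."""
    freqs = fragment_kmer_frequencies(fragment, profile.k)
    return float(freqs @ profile.scores)


def classify(fragment: Fragment, db: ProfileDatabase) -> Assignment:
    """Assign a fragment to the best-scoring profile in the database.

    Ties break to the lexicographically smallest ref_id.  With a single
    profile the runner-up is undefined and quality is +inf.
    """
    if len(db) == 0:
        raise ValueError("empty profile database")
    freqs = fragment_kmer_frequencies(fragment, db.k)
    return _assign(fragment.frag_id, db.score_matrix() @ freqs, db)


def _assign(frag_id: str, scores: np.ndarray, db: ProfileDatabase) -> Assignment:
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], db.profiles[i].ref_id))
    best = order[0]
    if len(order) == 1:
        return Assignment(
            frag_id=frag_id,
            best_ref_id=db.profiles[best].ref_id,
            best_score=float(scores[best]),
            quality=math.inf,
            classified=True,
        )
    second = order[1]
    return Assignment(
        frag_id=frag_id,
        best_ref_id=db.profiles[best].ref_id,
        best_score=float(scores[best]),
        second_ref_id=db.profiles[second].ref_id,
        second_score=float(scores[second]),
        quality=float(scores[best] - scores[second]),
        classified=True,
    )


def classify_all(fragments: list[Fragment], db: ProfileDatabase) -> list[Assignment]:
    """Classify a batch; unclassifiable fragments yield sentinel assignments."""
    matrix = db.score_matrix()
    out = []
    for frag in fragments:
        try:
            freqs = fragment_kmer_frequencies(frag, db.k)
        except UnclassifiableFragment:
            out.append(Assignment(frag_id=frag.frag_id, best_ref_id=None))
            continue
        out.append(_assign(frag.frag_id, matrix @ freqs, db))
    return out


def apply_quality_threshold(assignments: list[Assignment], p: float) -> list[Assignment]:
    """Keep the top p% of each assigned class by quality; relabel the rest unknown.

    Within each class the ceil(p/100 * n) highest-quality assignments stay
    classified (quality ties broken by frag_id, ascending, for
    determinism).  Unclassifiable assignments pass through untouched.
    """
    if not 0 < p <= 100:
        raise ValueError("p must be in (0, 100]")
    by_class: dict[str, list[Assignment]] = {}
    for a in assignments:
        if not a.unclassifiable:
            by_class.setdefault(a.best_ref_id, []).append(a)
    keep: set[str] = set()
    for members in by_class.values():
        members.sort(key=lambda a: (-a.quality, a.frag_id))
        n_keep = math.ceil(p / 100 * len(members))
        keep.update(a.frag_id for a in members[:n_keep])
    return [
        a if a.unclassifiable else replace(a, classified=a.frag_id in keep)
        for a in assignments
    ]
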