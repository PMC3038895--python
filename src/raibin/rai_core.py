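"""Relative abundance index (RAI) profiles.

A genome signature is built by comparing the observed probability of each
k-mer with its probability expected under a hierarchy of Markov
assumptions on the same sequence.  For order i (0 <= i <= k-2) the score
of word x_1..x_k is the log-odds

    rai_i = log2 [ P(x_1..x_k) P(x_{k-i}..x_{k-1})
                   / ( P(x_{k-i}..x_k) P(x_1..x_{k-1}) ) ],

where the length-i suffix for i = 0 is the empty word with probability 1,
so rai_0 tests the independence assumption P(x_k | x_1..x_{k-1}) = P(x_k)
and rai_i generally tests the order-i Markov assumption.  The profile
score of a word is the superposition sum over all orders i = 0..k-2:
positive for over-represented words, negative for under-represented ones,
and identically zero when observed counts are uniform at every length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .kmer_stats import (
    DEFAULT_PSEUDOCOUNT,
    KmerCountTable,
    count_kmers,
    kmer_index,
)

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import Fragment, ReferenceRecord

__all__ = ["RAIProfile", "rai_order", "rai_superposed", "build_profile", "profile_scores"]


@dataclass
class RAIProfile:
    """Superposed log-odds scores of one taxon: 4^k values, lexicographic k-mer order."""

    ref_id: str
    k: int
    scores: np.ndarray
    trained_length: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (4**self.k,):
            raise ValueError(
                f"profile {self.ref_id!r}: expected {4**self.k} scores, "
                f"got {self.scores.shape}"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValueError(f"profile {self.ref_id!r} has non-finite scores")

    def score(self, word: str) -> float:
        return float(self.scores[kmer_index(word)])


def rai_order(table: KmerCountTable, word: str, i: int) -> float:
    """Order-i relative abundance index of ``word`` under ``table``.

    ``i`` ranges over 0..k-2.  The length-i suffix ends at position k-1
    (the empty word for i = 0, with probability 1); the length-(i+1)
    suffix ends at position k.
    """
    k = table.k
    if len(word) != k:
        raise ValueError(f"word length {len(word)} != table k {k}")
    if not 0 <= i <= k - 2:
        raise ValueError(f"order i={i} outside 0..{k - 2}")
    log_sfx_i = 0.0 if i == 0 else np.log2(table.probability(word[k - 1 - i : k - 1]))
    log_sfx_i1 = np.log2(table.probability(word[k - 1 - i : k]))
    return float(
        np.log2(table.probability(word))
        + log_sfx_i
        - log_sfx_i1
        - np.log2(table.probability(word[: k - 1]))
    )


def rai_superposed(table: KmerCountTable, word: str) -> float:
    """Total superposed score: sum of rai_order over i = 0..k-2."""
    return sum(rai_order(table, word, i) for i in range(table.k - 1))


def profile_scores(table: KmerCountTable) -> np.ndarray:
    """Vectorised superposed scores for all 4^k words of ``table``.

    Equivalent to calling :func:`rai_superposed` on every word; the word
    at index j has its leading base in the high-order digit, so the
    length-(k-1) prefix of word j is word j // 4 and its length-m suffix
    is word j % 4^m.
    """
    k = table.k
    idx = np.arange(4**k, dtype=np.int64)
    log_pk = table.log2_probability_vector(k)
    log_pk1 = table.log2_probability_vector(k - 1)[idx // 4]
    scores = np.zeros(4**k, dtype=np.float64)
    for i in range(k - 1):
        # suffix of length i ending at position k-1 lives inside the prefix
        log_sfx_i = 0.0 if i == 0 else table.log2_probability_vector(i)[(idx // 4) % 4**i]
        log_sfx_i1 = table.log2_probability_vector(i + 1)[idx % 4 ** (i + 1)]
        scores += log_pk + log_sfx_i - log_sfx_i1 - log_pk1
    return scores


def build_profile(
    source: "ReferenceRecord | list[Fragment] | list[str] | str",
    k: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ref_id: str | None = None,
    with_reverse_complement: bool = False,
) -> RAIProfile:
    """Train an :class:`RAIProfile` from a reference record, fragments, or raw strings."""
    sequences, inferred_id = _as_sequences(source)
    table = count_kmers(
        sequences, k, pseudocount=pseudocount, with_reverse_complement=with_reverse_complement
    )
    return RAIProfile(
        ref_id=ref_id if ref_id is not None else inferred_id,
        k=k,
        scores=profile_scores(table),
        trained_length=table.total_bp,
    )


def _as_sequences(source) -> tuple[list, str]:
    if isinstance(source, str):
        return [source], ""
    if hasattr(source, "sequence") and hasattr(source, "ref_id"):  # ReferenceRecord
        return [source.sequence], source.ref_id
    seqs = []
    for item in source:
        seqs.append(item.sequence if hasattr(item, "sequence") else item)
    return seqs, ""
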