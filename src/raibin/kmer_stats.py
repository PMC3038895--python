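"""Oligomer counting over a sequence collection.

Counts every window of length 1..k that consists solely of A, C, G, T;
windows containing an N (or any non-ACGT symbol, which upstream I/O maps
to N) are skipped independently at each length.  Counts accumulate across
all sequences in the collection, so a collection behaves like one taxon.

Probabilities are add-pseudocount smoothed relative frequencies,

    P(w) = (count(w) + c) / (windows(|w|) + c * 4^|w|),

which keeps every word probability strictly positive (a prerequisite for
the log-odds scores built on top) while leaving the stored counts raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_PSEUDOCOUNT",
    "KmerCountTable",
    "count_kmers",
    "encode_sequence",
    "kmer_index",
    "index_to_kmer",
]

#: Default smoothing constant.  Heavy smoothing (e.g. add-one) puts a far
#: larger pseudo-mass fraction on the 4^k k-mer level than on the shorter
#: lengths, which biases the log-odds of common words downward and can
#: dominate the taxon signal outright; 0.01 keeps unseen-word
#: probabilities finite while leaving observed frequencies essentially raw.
DEFAULT_PSEUDOCOUNT = 0.01

_BASES = "ACGT"

# byte value -> 0..3 for ACGT (upper or lower case), -1 otherwise
_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a DNA string to an int8 array with A,C,G,T -> 0..3 and N/other -> -1."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def kmer_index(word: str) -> int:
    """Lexicographic index of ``word`` among all words of its length (A<C<G<T)."""
    idx = 0
    for ch in word:
        code = _ENC[ord(ch)]
        if code < 0:
            raise ValueError(f"word {word!r} contains a non-ACGT symbol")
        idx = idx * 4 + int(code)
    return idx


def index_to_kmer(index: int, m: int) -> str:
    """Inverse of :func:`kmer_index` for words of length ``m``."""
    if not 0 <= index < 4**m:
        raise ValueError(f"index {index} out of range for length {m}")
    out = []
    for _ in range(m):
        out.append(_BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


@dataclass
class KmerCountTable:
    """Raw window counts for every oligomer length 1..k plus smoothing state.

    ``counts[m]`` is the 4^m vector of window counts for length m (1-based
    keys); ``windows[m]`` the number of valid windows, i.e. ``counts[m].sum()``.
    """

    k: int
    counts: dict[int, np.ndarray]
    windows: dict[int, int]
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    total_bp: int = 0
    _pvec: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _log2p: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def probability(self, word: str) -> float:
        """Smoothed relative frequency of ``word`` (length 1..k, ACGT only)."""
        m = len(word)
        if not 1 <= m <= self.k:
            raise ValueError(f"word length {m} outside 1..{self.k}")
        idx = kmer_index(word)  # rejects N
        return self.probability_vector(m)[idx]

    def probability_vector(self, m: int) -> np.ndarray:
        """All 4^m smoothed probabilities for length ``m``, in lexicographic order."""
        if not 1 <= m <= self.k:
            raise ValueError(f"length {m} outside 1..{self.k}")
        if m not in self._pvec:
            denom = self.windows[m] + self.pseudocount * 4**m
            if denom == 0:
                raise ValueError(
                    f"no {m}-mer windows and pseudocount 0: probabilities undefined"
                )
            self._pvec[m] = (self.counts[m] + self.pseudocount) / denom
        return self._pvec[m]

    def log2_probability_vector(self, m: int) -> np.ndarray:
        if m not in self._log2p:
            self._log2p[m] = np.log2(self.probability_vector(m))
        return self._log2p[m]


def count_kmers(
    sequences: list[str] | str,
    k: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    with_reverse_complement: bool = False,
) -> KmerCountTable:
    """Count all oligomers of length 1..k across a sequence collection.

    Parameters
    ----------
    sequences
        One DNA string or a list of them; counts accumulate over the whole
        collection (windows never span sequence boundaries).
    k
        Maximum oligomer length, >= 2.
    pseudocount
        Smoothing constant added per word at probability time.
    with_reverse_complement
        Also count every window on the reverse complement strand, for
        strand-invariant profiles.  Off by default: the scores downstream
        are directional.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = {m: np.zeros(4**m, dtype=np.int64) for m in range(1, k + 1)}
    windows = dict.fromkeys(range(1, k + 1), 0)
    total_bp = 0

    for seq in sequences:
        enc = seq if isinstance(seq, np.ndarray) else encode_sequence(seq)
        total_bp += enc.size
        strands = [enc]
        if with_reverse_complement:
            rc = enc[::-1].copy()
            good = rc >= 0
            rc[good] = 3 - rc[good]
            strands.append(rc)
        for strand in strands:
            _accumulate(strand, k, counts, windows)

    if windows[k] == 0:
        raise ValueError(
            f"insufficient sequence: no valid window of length {k} in the collection"
        )
    return KmerCountTable(
        k=k, counts=counts, windows=windows, pseudocount=pseudocount, total_bp=total_bp
    )


def _accumulate(enc: np.ndarray, k: int, counts: dict, windows: dict) -> None:
    n = enc.size
    valid = enc >= 0
    codes = np.where(valid, enc, 0).astype(np.int64)
    # extend codes/validity window-by-window: length-m windows derive from m-1
    win_codes = codes
    win_valid = valid
    for m in range(1, k + 1):
        if m > 1:
            if win_codes.size <= 1:
                break
            win_codes = win_codes[:-1] * 4 + codes[m - 1 :]
            win_valid = win_valid[:-1] & valid[m - 1 :]
        if win_codes.size == 0:
            break
        sel = win_codes[win_valid]
        if sel.size:
            counts[m] += np.bincount(sel, minlength=4**m)
            windows[m] += int(sel.size)


def probability(table: KmerCountTable, word: str) -> float:
    """Module-level alias for :meth:`KmerCountTable.probability`."""
    return table.probability(word)
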