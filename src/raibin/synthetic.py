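"""Seeded synthetic data: Markov-chain genomes, rank trees, fragment sets.

Real microbial genomes carry pervasive, taxon-specific oligonucleotide
usage biases that decay with taxonomic distance.  The generator emulates
exactly that and nothing else: each taxon is an order-m Markov chain over
ACGT, children inherit the parent's transition table perturbed by a
multiplicative log-normal factor (the ``divergence`` scale) and
renormalised, so compositional similarity decreases with distance in the
rank tree.  There are no genes, repeats, GC skews, read errors or
chimeras — tests passing here show the statistical machinery works, not
that real genomes are this easy.

All randomness flows from one root seed through ``numpy`` SeedSequence
spawning, so every artefact is reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import RANKS, Fragment, Lineage, ReferenceRecord

__all__ = [
    "MarkovSource",
    "simulate_genome",
    "perturb_source",
    "random_source",
    "make_taxonomy_fixture",
    "sample_fragments",
]

_BASES = "ACGT"

#: Conditions of the standard synthetic study: an 8-species fixture
#: (2 phyla x 2 families x 2 genera x 1 species), order-3 sources,
#: 500 kbp genomes, sibling divergence 0.35 per tree edge.  Order 3 gives
#: the chains genuine higher-order structure — the kind of signal a
#: higher-order log-odds signature exists to exploit; order-0/1 sources
#: differ mostly in base composition, which the signature cancels.
DEFAULT_FANOUT = {"class": 1, "order": 1, "family": 2, "genus": 2, "species": 1}
DEFAULT_GENOME_LENGTH = 500_000
DEFAULT_ORDER = 3
DEFAULT_DIVERGENCE = 0.35


@dataclass
class MarkovSource:
    """An order-m Markov chain over ACGT.

    ``transition`` has shape (4^order, 4): row c is the distribution of
    the next base given context index c (lexicographic, A<C<G<T).  The
    ``seed`` makes :func:`simulate_genome` deterministic.
    """

    order: int
    transition: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=np.float64)
        if self.transition.shape != (4**self.order, 4):
            raise ValueError(
                f"transition shape {self.transition.shape} != ({4 ** self.order}, 4)"
            )
        if np.any(self.transition < 0):
            raise ValueError("transition probabilities must be non-negative")
        rowsums = self.transition.sum(axis=1)
        if np.any(rowsums == 0):
            raise ValueError("degenerate transition row (all zeros)")
        self.transition = self.transition / rowsums[:, None]


def random_source(order: int, seed: int, concentration: float = 1.0) -> MarkovSource:
    """A source with Dirichlet(concentration)-distributed transition rows."""
    rng = np.random.default_rng(seed)
    trans = rng.dirichlet([concentration] * 4, size=4**order)
    return MarkovSource(order=order, transition=trans, seed=seed)


def perturb_source(source: MarkovSource, divergence: float, seed: int) -> MarkovSource:
    """Derive a child source: multiply rows by exp(divergence * N(0,1)), renormalise.

    divergence = 0 returns the parent's table unchanged (a child
    statistically indistinguishable from its parent).
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(source.transition.shape)
    trans = source.transition * np.exp(divergence * noise)
    return MarkovSource(order=source.order, transition=trans, seed=seed)


def simulate_genome(source: MarkovSource, length: int) -> str:
    """Generate a genome of ``length`` bp from the chain, deterministic given source.seed.

    The initial context is drawn uniformly over the 4^order contexts.
    """
    if length < source.order + 1:
        raise ValueError(f"length {length} < order + 1 = {source.order + 1}")
    rng = np.random.default_rng(source.seed)
    cum = np.cumsum(source.transition, axis=1)
    cum[:, -1] = 1.0  # guard against round-off
    n_ctx = 4**source.order
    ctx = int(rng.integers(n_ctx)) if source.order > 0 else 0
    # the chain is inherently sequential; plain-Python state keeps the loop tight
    rows = cum.tolist()
    u = rng.random(length).tolist()
    out = bytearray(length)
    bases = b"ACGT"
    for i, x in enumerate(u):
        r = rows[ctx]
        b = (x >= r[0]) + (x >= r[1]) + (x >= r[2])
        out[i] = bases[b]
        ctx = (ctx * 4 + b) % n_ctx
    return out.decode("ascii")


def sample_fragments(
    genome: str | ReferenceRecord,
    n: int,
    length: int,
    seed: int,
    lineage: Lineage | None = None,
    id_prefix: str | None = None,
) -> list[Fragment]:
    """Draw n fragments of fixed length at independent uniform start positions.

    Fragments may overlap.  The truth lineage (from ``lineage`` or the
    reference record) is attached to every fragment.
    """
    if isinstance(genome, ReferenceRecord):
        lineage = lineage if lineage is not None else genome.lineage
        id_prefix = id_prefix if id_prefix is not None else genome.ref_id
        genome = genome.sequence
    if length > len(genome):
        raise ValueError(f"fragment length {length} exceeds genome length {len(genome)}")
    prefix = id_prefix or "frag"
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(genome) - length + 1, size=n)
    return [
        Fragment(frag_id=f"{prefix}:{i}:{s}", sequence=genome[s : s + length], truth=lineage)
        for i, s in enumerate(starts)
    ]


def make_taxonomy_fixture(
    n_phyla: int = 2,
    fanout_per_rank: dict[str, int] | None = None,
    divergence: float = DEFAULT_DIVERGENCE,
    seed: int = 0,
    genome_length: int = DEFAULT_GENOME_LENGTH,
    order: int = DEFAULT_ORDER,
    return_sources: bool = False,
):
    """Build a rank tree of Markov sources and simulate one genome per species.

    Starting from a single random root table, every edge of the tree
    (phylum under the root, then class, order, family, genus, species)
    applies :func:`perturb_source`, so two leaves' compositional
    divergence grows with the rank of their lowest common ancestor.

    Returns ``(references, taxonomy)`` — one :class:`ReferenceRecord` per
    species plus the ref_id -> Lineage table — or, with
    ``return_sources``, ``(references, taxonomy, sources)`` where
    ``sources`` maps ref_id to the leaf's :class:`MarkovSource`.
    """
    fanout = dict(DEFAULT_FANOUT, **(fanout_per_rank or {}))
    if n_phyla < 1 or any(v < 1 for v in fanout.values()):
        raise ValueError("fanouts must be >= 1")

    root_ss = np.random.SeedSequence(seed)
    spawn = iter((s & 0x7FFFFFFF) for s in root_ss.generate_state(65_536, dtype=np.uint32).tolist())

    root = random_source(order, next(spawn))
    # ranks from broad to specific below the root
    levels = ["phylum", "class", "order", "family", "genus", "species"]
    leaves: list[tuple[dict[str, str], MarkovSource]] = []

    def grow(parent: MarkovSource, depth: int, names: dict[str, str]) -> None:
        rank = levels[depth]
        n_children = n_phyla if rank == "phylum" else fanout[rank]
        for j in range(n_children):
            child = perturb_source(parent, divergence, next(spawn))
            tag = f"{rank[0]}{j}"
            label = names.get(levels[depth - 1], "") + ("." if depth else "") + tag
            child_names = dict(names, **{rank: label or tag})
            if rank == "species":
                leaves.append((child_names, child))
            else:
                grow(child, depth + 1, child_names)

    grow(root, 0, {})

    references: list[ReferenceRecord] = []
    taxonomy: dict[str, Lineage] = {}
    sources: dict[str, MarkovSource] = {}
    for names, src in leaves:
        ref_id = names["species"]
        lin = Lineage.from_dict(names)
        src.seed = next(spawn)
        references.append(
            ReferenceRecord(ref_id=ref_id, sequence=simulate_genome(src, genome_length), lineage=lin)
        )
        taxonomy[ref_id] = lin
        sources[ref_id] = src
    if return_sources:
        return references, taxonomy, sources
    return references, taxonomy
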