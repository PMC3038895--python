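"""On-disk conventions: FASTA references and fragments, taxonomy tables,
the profile database, and assignment tables.

Taxonomy tables are TSV with a ``ref_id`` column plus the six ranks
species, genus, family, order, class, phylum ("-" or empty = missing).
The profile database (.raidb) is a line-oriented text format: a header
with magic string, format version, k and profile count, then one block
per profile carrying ref_id, lineage, trained length, and exactly 4^k
scores in lexicographic k-mer order (A<C<G<T) as full-precision decimal
text, so a write -> read -> write cycle is byte-identical.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .rai_core import RAIProfile

__all__ = [
    "RANKS",
    "Lineage",
    "ReferenceRecord",
    "Fragment",
    "ProfileDatabase",
    "read_references",
    "read_taxonomy",
    "read_fragments",
    "write_fasta",
    "write_taxonomy",
    "write_profile_db",
    "read_profile_db",
    "write_assignments",
]

#: Taxonomic ranks, most specific first.
RANKS = ("species", "genus", "family", "order", "class", "phylum")

_MAGIC = "#RAIDB"
_VERSION = 1
_MISSING = "-"

_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class Lineage:
    """Names at the six ranks; ``None`` marks a missing rank."""

    species: str | None = None
    genus: str | None = None
    family: str | None = None
    order: str | None = None
    class_: str | None = None
    phylum: str | None = None

    def get(self, rank: str) -> str | None:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, "class_" if rank == "class" else rank)

    def as_fields(self) -> list[str]:
        return [self.get(r) or _MISSING for r in RANKS]

    @classmethod
    def from_fields(cls, fields: list[str]) -> "Lineage":
        vals = [None if f in ("", _MISSING) else f for f in fields]
        return cls(
            species=vals[0], genus=vals[1], family=vals[2],
            order=vals[3], class_=vals[4], phylum=vals[5],
        )

    @classmethod
    def from_dict(cls, d: dict) -> "Lineage":
        return cls.from_fields([d.get(r) or _MISSING for r in RANKS])


@dataclass
class ReferenceRecord:
    """One reference organism: all replicons concatenated, plus its lineage."""

    ref_id: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.ref_id!r} has an empty sequence")


@dataclass
class Fragment:
    """A query sequence; ``truth`` carries the source lineage for evaluation."""

    frag_id: str
    sequence: str
    truth: Lineage | None = None


def clean_sequence(sequence: str) -> str:
    """Uppercase and map every non-ACGT IUPAC symbol to N."""
    return _NON_ACGTN.sub("N", sequence.upper())


# ---------------------------------------------------------------------------
# FASTA + taxonomy


def read_taxonomy(taxonomy_path) -> dict[str, Lineage]:
    """Read a TSV taxonomy table (header: ref_id + the six ranks)."""
    lines = Path(taxonomy_path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty taxonomy table: {taxonomy_path}")
    header = lines[0].rstrip("\n").split("\t")
    if header[0] != "ref_id":
        raise ValueError(f"taxonomy table must start with a 'ref_id' column, got {header[0]!r}")
    missing_cols = [r for r in RANKS if r not in header]
    if missing_cols:
        raise ValueError(f"taxonomy table missing rank column(s): {', '.join(missing_cols)}")
    col = {name: i for i, name in enumerate(header)}
    out: dict[str, Lineage] = {}
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        ref_id = fields[col["ref_id"]]
        out[ref_id] = Lineage.from_fields(
            [fields[col[r]] if col[r] < len(fields) else _MISSING for r in RANKS]
        )
    return out


def read_references(
    fasta_path,
    taxonomy_path,
    concat_by: str | None = None,
) -> list[ReferenceRecord]:
    """Read reference genomes, grouping replicons of one organism together.

    ``concat_by`` is an optional regex applied to each FASTA id; its first
    group (or full match) names the organism, so e.g. ``r"^([^|]+)"``
    groups ``X|chr1`` and ``X|chr2`` under ``X``.  By default each FASTA
    record is its own organism.  Grouped sequences are concatenated
    plainly, in file order.
    """
    taxonomy = read_taxonomy(taxonomy_path)
    pattern = re.compile(concat_by) if concat_by else None
    groups: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        rid = rec.id
        if pattern is not None:
            m = pattern.search(rid)
            if m is None:
                raise ValueError(f"grouping pattern {concat_by!r} does not match id {rid!r}")
            rid = m.group(1) if m.groups() else m.group(0)
        groups.setdefault(rid, []).append(clean_sequence(str(rec.seq)))
    if not groups:
        raise ValueError(f"empty FASTA: {fasta_path}")
    records = []
    for rid, seqs in groups.items():
        if rid not in taxonomy:
            raise ValueError(f"no taxonomy row for reference {rid!r}")
        records.append(ReferenceRecord(ref_id=rid, sequence="".join(seqs), lineage=taxonomy[rid]))
    return records


def read_fragments(fasta_path, taxonomy: dict[str, Lineage] | None = None) -> list[Fragment]:
    """Read query fragments; optional taxonomy keyed by fragment id attaches truths."""
    frags = [
        Fragment(
            frag_id=rec.id,
            sequence=clean_sequence(str(rec.seq)),
            truth=(taxonomy or {}).get(rec.id),
        )
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    if not frags:
        raise ValueError(f"empty FASTA: {fasta_path}")
    return frags


def write_fasta(records, path, width: int = 70) -> None:
    """Write (id, sequence) pairs, ReferenceRecords or Fragments as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                rid, seq = rec
            else:
                rid = getattr(rec, "ref_id", None) or rec.frag_id
                seq = rec.sequence
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_taxonomy(lineages: dict[str, Lineage], path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_id\t" + "\t".join(RANKS) + "\n")
        for rid, lin in lineages.items():
            fh.write(rid + "\t" + "\t".join(lin.as_fields()) + "\n")


# ---------------------------------------------------------------------------
# Profile database


@dataclass
class ProfileDatabase:
    """A set of same-k RAI profiles with the lineage of every profile."""

    k: int
    profiles: list[RAIProfile]
    lineages: dict[str, Lineage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.ref_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ref_id in profile database")
        for p in self.profiles:
            if p.k != self.k:
                raise ValueError(f"profile {p.ref_id!r} has k={p.k}, database k={self.k}")
            if p.ref_id not in self.lineages:
                raise ValueError(f"profile {p.ref_id!r} has no lineage entry")

    def __len__(self) -> int:
        return len(self.profiles)

    def lineage_of(self, ref_id: str) -> Lineage:
        return self.lineages[ref_id]

    def score_matrix(self) -> np.ndarray:
        """Profiles stacked row-wise: shape (n_profiles, 4^k)."""
        return np.vstack([p.scores for p in self.profiles])


def write_profile_db(db: ProfileDatabase, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC}\tversion={_VERSION}\tk={db.k}\tprofiles={len(db.profiles)}\n")
        for p in db.profiles:
            lin = "\t".join(db.lineages[p.ref_id].as_fields())
            fh.write(f">{p.ref_id}\t{lin}\t{p.trained_length}\n")
            fh.write(" ".join(repr(float(s)) for s in p.scores) + "\n")


def read_profile_db(path) -> ProfileDatabase:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(_MAGIC + "\t"):
        raise ValueError(f"{path}: not a profile database (bad magic)")
    header = dict(kv.split("=", 1) for kv in lines[0].split("\t")[1:])
    if int(header.get("version", -1)) != _VERSION:
        raise ValueError(f"{path}: unsupported profile database version {header.get('version')}")
    k = int(header["k"])
    n = int(header["profiles"])
    profiles: list[RAIProfile] = []
    lineages: dict[str, Lineage] = {}
    pos = 1
    for _ in range(n):
        if pos + 1 >= len(lines):
            raise ValueError(f"{path}: truncated profile database")
        meta = lines[pos]
        score_line = lines[pos + 1]
        if not meta.startswith(">"):
            raise ValueError(f"{path}: malformed profile header at line {pos + 1}")
        fields = meta[1:].split("\t")
        ref_id, lineage_fields, trained = fields[0], fields[1:7], int(fields[7])
        scores = np.array([float(s) for s in score_line.split(" ")], dtype=np.float64)
        if scores.size != 4**k:
            raise ValueError(
                f"{path}: truncated profile database (profile {ref_id!r}: "
                f"{scores.size} of {4**k} scores)"
            )
        profiles.append(RAIProfile(ref_id=ref_id, k=k, scores=scores, trained_length=trained))
        lineages[ref_id] = Lineage.from_fields(lineage_fields)
        pos += 2
    if len(profiles) != n:
        raise ValueError(f"{path}: truncated profile database")
    return ProfileDatabase(k=k, profiles=profiles, lineages=lineages)


# ---------------------------------------------------------------------------
# Assignment tables


def write_assignments(assignments, db: ProfileDatabase, path, config_comment: str | None = None) -> None:
    """Write one TSV row per fragment: best hit, lineage, scores, classified flag.

    Unclassifiable fragments (shorter than k or all-N) get empty score
    fields; fragments thresholded out keep their best-hit lineage but are
    flagged ``unknown``.
    """
    cols = ["frag_id", "ref_id", *RANKS, "membership_score", "quality_score", "classified"]
    with open(path, "w") as fh:
        if config_comment:
            for line in config_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for a in assignments:
            if a.best_ref_id is None:  # unclassifiable
                row = [a.frag_id, _MISSING, *([_MISSING] * 6), "", "", "unclassifiable"]
            else:
                lin = db.lineages[a.best_ref_id]
                q = "inf" if math.isinf(a.quality) else repr(a.quality)
                row = [
                    a.frag_id,
                    a.best_ref_id,
                    *lin.as_fields(),
                    repr(a.best_score),
                    q,
                    "true" if a.classified else "unknown",
                ]
            fh.write("\t".join(row) + "\n")
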