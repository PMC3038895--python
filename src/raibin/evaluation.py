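"""Rank-aware evaluation: sensitivity/specificity, cross-validation harnesses.

Per class i at a given rank,

    Sn_i = TP_i / (TP_i + FN_i + U_i)      Sp_i = TP_i / (TP_i + FP_i)

with U_i the unclassified count of class i (unknowns punish sensitivity
but not specificity).  An assignment counts as a true positive at rank r
when the assigned profile's lineage matches the fragment's truth lineage
at r — so in clade-exclusion experiments, where the fragment's own taxon
is absent from the database, hitting a sister taxon at the parent rank
still counts as correct.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import Assignment, apply_quality_threshold
from .io_formats import RANKS, Lineage, ProfileDatabase, ReferenceRecord
from .rai_core import build_profile
from .refinement import RefinementConfig, iterative_binning
from .synthetic import sample_fragments

__all__ = [
    "ClassStats",
    "EvalReport",
    "score_assignments",
    "leave_one_out",
    "sensitivity_specificity_curve",
    "LeaveOneOutResult",
]


@dataclass
class ClassStats:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    u: int = 0

    @property
    def n_truth(self) -> int:
        return self.tp + self.fn + self.u

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_truth if self.n_truth else math.nan

    @property
    def specificity(self) -> float:
        # missing (not 0) when the class predicted nothing, to keep averages honest
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan


@dataclass
class EvalReport:
    """Confusion statistics per class at one rank."""

    rank: str
    classes: dict[str, ClassStats] = field(default_factory=dict)
    unresolvable: int = 0

    @property
    def accuracy(self) -> float:
        """Overall fraction of rank-resolvable fragments that are TPs."""
        n = sum(c.n_truth for c in self.classes.values())
        return sum(c.tp for c in self.classes.values()) / n if n else math.nan

    @property
    def mean_sensitivity(self) -> float:
        """Macro-average over classes with at least one truth fragment."""
        vals = [c.sensitivity for c in self.classes.values() if c.n_truth]
        return float(np.mean(vals)) if vals else math.nan

    @property
    def mean_specificity(self) -> float:
        """Macro-average over classes where specificity is defined."""
        vals = [c.specificity for c in self.classes.values() if (c.tp + c.fp)]
        return float(np.mean(vals)) if vals else math.nan

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": name, "rank": self.rank,
                "TP": c.tp, "FP": c.fp, "FN": c.fn, "U": c.u,
                "Sn": c.sensitivity, "Sp": c.specificity,
            }
            for name, c in sorted(self.classes.items())
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def merge(self, other: "EvalReport") -> "EvalReport":
        if other.rank != self.rank:
            raise ValueError("cannot merge reports at different ranks")
        merged = EvalReport(rank=self.rank, unresolvable=self.unresolvable + other.unresolvable)
        for name in set(self.classes) | set(other.classes):
            a = self.classes.get(name, ClassStats())
            b = other.classes.get(name, ClassStats())
            merged.classes[name] = ClassStats(
                tp=a.tp + b.tp, fp=a.fp + b.fp, fn=a.fn + b.fn, u=a.u + b.u
            )
        return merged


def score_assignments(
    assignments: list[Assignment],
    truths: dict[str, Lineage],
    db: ProfileDatabase,
    rank: str,
) -> EvalReport:
    """Tally TP/FP/FN/U at one rank from assignments plus truth lineages."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    report = EvalReport(rank=rank)

    def stats(name: str) -> ClassStats:
        return report.classes.setdefault(name, ClassStats())

    for a in assignments:
        truth = truths.get(a.frag_id)
        if truth is None:
            raise ValueError(f"no truth lineage for fragment {a.frag_id!r}")
        truth_name = truth.get(rank)
        assigned_name = (
            None if a.unclassifiable else db.lineage_of(a.best_ref_id).get(rank)
        )
        if truth_name is None and assigned_name is None:
            report.unresolvable += 1
            continue
        if a.unclassifiable or not a.classified:
            if truth_name is not None:
                stats(truth_name).u += 1
            else:
                report.unresolvable += 1
            continue
        if truth_name == assigned_name:
            stats(truth_name).tp += 1
        else:
            if truth_name is not None:
                stats(truth_name).fn += 1
            if assigned_name is not None:
                stats(assigned_name).fp += 1
    return report


@dataclass
class LeaveOneOutResult:
    final: EvalReport
    first_pass: EvalReport
    per_reference: dict[str, EvalReport] = field(default_factory=dict)


def leave_one_out(
    references: list[ReferenceRecord],
    frag_len: int,
    n_frags: int = 3000,
    mode: str = "self",
    cfg: RefinementConfig | None = None,
    seed: int = 0,
    refine: bool = True,
) -> LeaveOneOutResult:
    """Test each reference in turn: bin its fragments, score rank-aware.

    mode "self" keeps every profile — including the test genome's own —
    in the database and scores at species rank; it is the sanity ceiling
    (fragments should return to their own genome).  mode
    "exclude_clade@<rank>" removes every reference sharing the test
    genome's taxon at <rank> and scores one rank up, crediting
    assignments to sister taxa; ``exclude_clade@species`` is the classic
    leave-one-out experiment.  In exclude mode only references with an
    eligible sister (another reference matching at the scoring rank) are
    tested.
    """
    cfg = cfg or RefinementConfig()
    if mode == "self":
        exclude_rank, score_rank = None, "species"
    elif mode.startswith("exclude_clade@"):
        exclude_rank = mode.split("@", 1)[1]
        if exclude_rank not in RANKS or exclude_rank == "phylum":
            raise ValueError(f"cannot exclude clade at rank {exclude_rank!r}")
        score_rank = RANKS[RANKS.index(exclude_rank) + 1]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ss = np.random.SeedSequence(seed)
    frag_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(len(references)).tolist()]

    # each reference's seed profile is identical across folds; train once
    profile_of = {
        r.ref_id: build_profile(r, cfg.k, pseudocount=cfg.pseudocount) for r in references
    }

    final_total = EvalReport(rank=score_rank)
    first_total = EvalReport(rank=score_rank)
    per_reference: dict[str, EvalReport] = {}

    for test_ref, frag_seed in zip(references, frag_seeds):
        if frag_len > len(test_ref.sequence):
            warnings.warn(
                f"reference {test_ref.ref_id!r} shorter than fragment length; skipped",
                stacklevel=2,
            )
            continue
        if exclude_rank is None:
            train = list(references)
        else:
            held_taxon = test_ref.lineage.get(exclude_rank)
            train = [r for r in references if r.lineage.get(exclude_rank) != held_taxon]
        if not train:
            continue
        # sister requirement: somebody in the training set matches at the scoring rank
        target = test_ref.lineage.get(score_rank)
        if exclude_rank is not None and not any(
            r.lineage.get(score_rank) == target for r in train
        ):
            continue

        db = ProfileDatabase(
            k=cfg.k,
            profiles=[profile_of[r.ref_id] for r in train],
            lineages={r.ref_id: r.lineage for r in train},
        )
        frags = sample_fragments(test_ref, n_frags, frag_len, seed=frag_seed)
        truths = {f.frag_id: f.truth for f in frags}
        if refine:
            result = iterative_binning(frags, db, cfg)
            final = score_assignments(result.assignments, truths, result.db, score_rank)
            first = score_assignments(result.first_pass_assignments, truths, db, score_rank)
        else:
            from .classifier import classify_all

            assignments = classify_all(frags, db)
            final = first = score_assignments(assignments, truths, db, score_rank)
        per_reference[test_ref.ref_id] = final
        final_total = final_total.merge(final)
        first_total = first_total.merge(first)

    return LeaveOneOutResult(final=final_total, first_pass=first_total, per_reference=per_reference)


def sensitivity_specificity_curve(
    assignments: list[Assignment],
    truths: dict[str, Lineage],
    db: ProfileDatabase,
    rank: str,
    p_grid: list[float],
) -> list[tuple[float, float, float]]:
    """(p, mean Sn, mean Sp) after top-p% quality thresholding, per grid point."""
    curve = []
    for p in p_grid:
        report = score_assignments(apply_quality_threshold(assignments, p), truths, db, rank)
        curve.append((p, report.mean_sensitivity, report.mean_specificity))
    return curve
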