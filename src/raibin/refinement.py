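"""Iterative refinement of profiles from the fragments themselves.

A hard-assignment EM-style loop: classify every fragment against the
current profiles, then rebuild the profile of each class from the
fragments assigned to it — but only when those fragments total more than
``update_min_bp`` (25 kbp by default), so thinly populated classes keep
their seed model.  The loop stops when the mean best membership score
over classified fragments changes by less than ``stop_tol`` (1%)
relative to the previous iteration, or at ``max_iters``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .classifier import Assignment, classify_all
from .io_formats import Fragment, ProfileDatabase
from .kmer_stats import DEFAULT_PSEUDOCOUNT
from .rai_core import build_profile

logger = logging.getLogger(__name__)

__all__ = ["RefinementConfig", "BinningResult", "iterative_binning", "should_stop"]


@dataclass(frozen=True)
class RefinementConfig:
    """Knobs of the refinement loop.

    stop_tol
        Relative change in mean membership score below which the loop
        stops (default 0.01, the 1% rule).
    update_min_bp
        Minimum summed length (bp) of a class's assigned fragments before
        its profile is retrained (default 25,000).
    max_iters
        Hard cap guaranteeing termination (refinement converges in a
        handful of iterations in practice).
    pool_seed_counts
        When True, retraining pools the assigned fragments with the
        class's seed sequences instead of replacing the model outright.
    """

    stop_tol: float = 0.01
    update_min_bp: int = 25_000
    max_iters: int = 30
    k: int = 7
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    pool_seed_counts: bool = False

    def __post_init__(self) -> None:
        if self.stop_tol <= 0:
            raise ValueError("stop_tol must be > 0")
        if self.update_min_bp < self.k:
            raise ValueError("update_min_bp must be >= k")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class BinningResult:
    assignments: list[Assignment]
    avg_scores: list[float]
    iterations: int
    stopped_by: str  # "tolerance" | "max_iters"
    db: ProfileDatabase = field(repr=False, default=None)
    first_pass_assignments: list[Assignment] = field(repr=False, default=None)


def should_stop(avg_scores: list[float], stop_tol: float) -> bool:
    """The 1% rule on the last two mean scores: stop when |cur/prev - 1| < tol."""
    if len(avg_scores) < 2:
        return False
    prev, cur = avg_scores[-2], avg_scores[-1]
    return abs(cur / prev - 1.0) < stop_tol


def iterative_binning(
    fragments: list[Fragment],
    seed_db: ProfileDatabase,
    cfg: RefinementConfig | None = None,
    seed_sequences: dict[str, list[str]] | None = None,
) -> BinningResult:
    """Run classify/update rounds from a seed database until the scores settle.

    ``seed_sequences`` (ref_id -> raw sequences) is only consulted when
    ``cfg.pool_seed_counts`` is set.
    """
    cfg = cfg or RefinementConfig()
    if seed_db.k != cfg.k:
        raise ValueError(f"seed database k={seed_db.k} differs from config k={cfg.k}")
    db = seed_db
    avg_scores: list[float] = []
    assignments: list[Assignment] = []
    first_pass: list[Assignment] | None = None
    stopped_by = "max_iters"

    for it in range(1, cfg.max_iters + 1):
        assignments = classify_all(fragments, db)
        classified = [a for a in assignments if not a.unclassifiable]
        if not classified:
            raise ValueError("no classifiable fragment in the input")
        if first_pass is None:
            first_pass = assignments
        avg_scores.append(sum(a.best_score for a in classified) / len(classified))

        if should_stop(avg_scores, cfg.stop_tol):
            stopped_by = "tolerance"
            break
        if it == cfg.max_iters:
            break

        db, n_updated = _update_profiles(fragments, assignments, db, cfg, seed_sequences)
        logger.info(
            "iteration %d: avg score %.6g, %d class(es) retrained",
            it, avg_scores[-1], n_updated,
        )

    return BinningResult(
        assignments=assignments,
        avg_scores=avg_scores,
        iterations=len(avg_scores),
        stopped_by=stopped_by,
        db=db,
        first_pass_assignments=first_pass,
    )


def _update_profiles(fragments, assignments, db, cfg, seed_sequences):
    frag_by_id = {f.frag_id: f for f in fragments}
    assigned: dict[str, list[Fragment]] = {}
    for a in assignments:
        if not a.unclassifiable:
            assigned.setdefault(a.best_ref_id, []).append(frag_by_id[a.frag_id])
    new_profiles = []
    n_updated = 0
    for prof in db.profiles:
        members = assigned.get(prof.ref_id, [])
        total_bp = sum(len(f.sequence) for f in members)
        if total_bp > cfg.update_min_bp:
            seqs: list[str] = [f.sequence for f in members]
            if cfg.pool_seed_counts and seed_sequences:
                seqs = seqs + list(seed_sequences.get(prof.ref_id, []))
            new_profiles.append(
                build_profile(seqs, cfg.k, pseudocount=cfg.pseudocount, ref_id=prof.ref_id)
            )
            n_updated += 1
        else:
            new_profiles.append(prof)
    return ProfileDatabase(k=db.k, profiles=new_profiles, lineages=db.lineages), n_updated
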