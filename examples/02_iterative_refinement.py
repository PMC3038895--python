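"""Refine imperfect seed profiles from the fragments themselves.

Seed profiles come from perturbed relatives of the true sources (the
usual metagenomics situation: the species in the sample are not in the
reference database, only their relatives are).  The classify/retrain
loop then adapts each class's profile to the fragments assigned to it,
and the mean membership score rises to a plateau.
"""

from raibin import RefinementConfig, iterative_binning, score_assignments
from raibin.io_formats import ProfileDatabase
from raibin.rai_core import build_profile
from raibin.synthetic import (
    make_taxonomy_fixture,
    perturb_source,
    sample_fragments,
    simulate_genome,
)

K = 7

refs, taxonomy, sources = make_taxonomy_fixture(seed=1, return_sources=True)
fragments = []
for i, ref in enumerate(refs):
    fragments.extend(sample_fragments(ref, 1000, 400, seed=100 + i))
truths = {f.frag_id: f.truth for f in fragments}

# seed database: profiles of perturbed RELATIVES, not the true genomes
seed_profiles = []
for i, ref in enumerate(refs):
    relative = perturb_source(sources[ref.ref_id], 0.35, seed=500 + i)
    relative.seed = 900 + i
    seed_profiles.append(build_profile(simulate_genome(relative, 500_000), K, ref_id=ref.ref_id))
seed_db = ProfileDatabase(k=K, profiles=seed_profiles, lineages=taxonomy)

result = iterative_binning(fragments, seed_db, RefinementConfig())

print(f"converged after {result.iterations} iterations ({result.stopped_by})")
for it, score in enumerate(result.avg_scores, start=1):
    print(f"  iteration {it}: mean membership score {score:.4f}")

first = score_assignments(result.first_pass_assignments, truths, seed_db, "species")
final = score_assignments(result.assignments, truths, result.db, "species")
print(f"\nspecies-level accuracy before refinement: {100 * first.accuracy:.2f}%")
print(f"species-level accuracy after refinement:  {100 * final.accuracy:.2f}%")
print(
    "\nThe score trajectory saturates once retrained profiles describe the "
    "fragment clusters as well as they can; the loop stops when the relative "
    "change drops under 1%."
)
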