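"""De novo structural-variant consensus filtering with a full audit trail.

Plants true de novo deletions alongside inherited, artifactual,
repeat-region and single-caller decoys, then runs the four-stage filter:
dual-caller 50% reciprocal-overlap consensus, parental subtraction
(confident calls and low-confidence candidates alike), exclusion-track
annotation, and trio coverage-pattern comparison.
"""

from collections import Counter

from triodnv.sv_consensus import run_sv_pipeline
from triodnv.synth import SyntheticCohortConfig, simulate_sv_data, simulate_tracks

config = SyntheticCohortConfig(seed=13)
tracks = simulate_tracks(config)
sim = simulate_sv_data(config, tracks)

candidates = run_sv_pipeline(sim.child_callsets, sim.parental_calls,
                             tracks.trackset, sim.coverage)

truth = {(t.chrom, t.start): t for t in sim.truths}
print(f"planted: {Counter(t.category for t in sim.truths)}")
print(f"{len(candidates)} caller-A candidates entered the pipeline\n")
for cand in candidates:
    t = truth[(cand.call_a.chrom, cand.call_a.start)]
    fate = "SURVIVES" if cand.final else f"removed at {cand.first_failed}"
    print(f"  {cand.call_a.chrom}:{cand.call_a.start}-{cand.call_a.end} "
          f"{cand.call_a.svtype} [{t.category}] -> {fate}")

final = [c for c in candidates if c.final]
print(f"\nfinal de novo SVs: {len(final)} "
      f"(planted true: {sum(1 for t in sim.truths if t.category == 'true_de_novo')})")
# Every removal is attributable to exactly one first-failing stage, so a
# reviewer can audit why each candidate dropped out instead of
# re-inspecting alignments manually.
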