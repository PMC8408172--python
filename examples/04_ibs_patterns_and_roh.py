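"""Classify double/single IBS regions and runs of homozygosity.

Full sibs share both homologs across ~25% of the genome (double IBS) and
exactly one across ~50%; runs of homozygosity flag inbreeding.  Both
patterns help separate full-sib from half-sib hypotheses.
"""

from haploshare import SimDesign, classify_ibs, coinciding_roh, find_roh, simulate_population

sim = simulate_population(SimDesign(templates={"FSIB": 1}, n_markers=1617, seed=3))
a, b = "FSIB0_A", "FSIB0_B"

track = classify_ibs(sim.genotypes.get(a), sim.genotypes.get(b), sim.map, min_length=10.0)
for cls in ("DOUBLE", "SINGLE", "NONE"):
    frac = track.fractions[cls]
    n = len(track.intervals[cls])
    print(f"{cls:6s}: {n:3d} regions >= 10 cM covering {100 * frac:5.1f}% of the genome")

roh_a = find_roh(sim.genotypes.get(a), sim.map, min_length=10.0, individual=a)
roh_b = find_roh(sim.genotypes.get(b), sim.map, min_length=10.0, individual=b)
_, shared_cm = coinciding_roh(roh_a, roh_b)
print(f"ROH >= 10 cM: {len(roh_a)} in {a}, {len(roh_b)} in {b}; "
      f"{shared_cm:.0f} cM coinciding")

# With unrelated, non-inbred parents the double-IBS fraction sits near the
# 25% full-sib expectation and ROH are rare; elevated double IBS or shared
# ROH would point at extra ancestry between the parents.
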