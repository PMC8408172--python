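"""Detect shared haplotype segments and compute SPLoSH for a tiny pair.

Builds a six-marker chromosome by hand, scans a pair of unphased genotypes
for identical-by-state segments, and sums segment lengths above thresholds.
"""

import numpy as np

from haploshare import GeneticMap, find_shared_segments
from haploshare.formats_io import ALLELE_CODES

gmap = GeneticMap(
    markers=tuple(f"m{i}" for i in range(1, 7)),
    chromosome=("1",) * 6,
    position=np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0]),
)


def geno(strings):
    return np.array([[ALLELE_CODES[s[0]], ALLELE_CODES[s[1]]] for s in strings], dtype=np.int8)


x = geno(["AB", "AA", "AB", "BB", "AA", "AB"])
y = geno(["AA", "AB", "BB", "AB", "BB", "AA"])  # clashes with x at m5

print("all maximal shared segments:")
for s in find_shared_segments(x, y, gmap, id_a="X", id_b="Y"):
    print(f"  chr{s.chromosome} {s.start_cM:.0f}-{s.end_cM:.0f} cM ({s.length_cM:.0f} cM)")

for t in (25.0, 40.0):
    splosh = sum(s.length_cM for s in find_shared_segments(x, y, gmap, min_length=t))
    print(f"SPLoSH at threshold {t:.0f} cM: {splosh:.0f} cM")

# The 30 cM segment m1-m4 survives the 25 cM threshold; the single-marker
# match at m6 has length 0 and never contributes.  With missing data at m5
# the clash disappears and the two segments would merge (missing bridges).
y_missing = y.copy()
y_missing[4] = [-1, -1]
merged = find_shared_segments(x, y_missing, gmap)
print(f"with m5 missing: one segment of {merged[0].length_cM:.0f} cM (bridged)")
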