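"""Scan an assembled sequence for microsatellite candidates.

A 50 kb synthetic contig carries twelve planted perfect repeats, one of
them with duplicated flanking sequence.  The funnel: scan -> drop
candidates with non-unique flanks -> size/repeat filter, ranked by repeat
count.
"""

import numpy as np

from msatpop.discovery import exclude_duplicates, filter_candidates, scan_ssrs
from msatpop.simulate import simulate_genome_with_ssrs

rng = np.random.default_rng(0)
planted = [{"motif": m, "n_repeats": int(rng.integers(10, 18))}
           for m in ["AG", "AC", "AT", "ATC"] * 3]
contigs, truth = simulate_genome_with_ssrs(
    length=50_000, planted=planted, seed=0, duplicate_flanks=1)

candidates = scan_ssrs(contigs, motif_lengths=(2, 3), min_repeats=10)
unique, excluded = exclude_duplicates(candidates, contigs)
selected = filter_candidates(unique, size_range=(10, 500), min_repeats=13)

print(f"planted repeats : {len(truth)}")
print(f"scanned         : {len(candidates)}")
print(f"unique flanks   : {len(unique)} ({len(excluded)} excluded)")
print(f"selected (>=13) : {len(selected)}")
for c in selected[:5]:
    print(f"  {c.contig}:{c.start}-{c.end}  ({c.motif})x{c.n_repeats}")
# The counts shrink monotonically down the funnel; the duplicated locus and
# its copy drop out at the flank-uniqueness step, exactly as primer pairs
# mapping to two genomic sites would.
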