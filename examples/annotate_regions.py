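"""Annotate candidate regions against a BED file of features.

Builds two regions and a tiny feature set in memory, then reports every
feature overlapping a region with its overlap length.
"""

import pandas as pd

from divscan.regions import Region, annotate_regions

regions = [
    Region(1, 5_900_001, 6_150_001, tests={"FST", "XPEHH"}),
    Region(2, 1_000_001, 1_100_001, tests={"FST", "IHS"}),
]

# features on the internal 1-based half-open axis (read_bed() produces
# exactly this frame from a standard 0-based BED file)
features = pd.DataFrame([
    {"chrom": 1, "start": 5_950_001, "end": 5_980_001, "name": "growth_gene_A"},
    {"chrom": 1, "start": 6_140_001, "end": 6_400_001, "name": "growth_gene_B"},
    {"chrom": 2, "start": 1_100_001, "end": 1_200_001, "name": "abutting_gene"},
])

for h in annotate_regions(regions, features):
    print(f"chr{h.region.chrom}:{h.region.start}-{h.region.end} "
          f"({'+'.join(sorted(h.region.tests))}) overlaps {h.feature} "
          f"by {h.overlap_bp} bp")
# growth_gene_A lies inside the first region (overlap = its full length);
# growth_gene_B only straddles its right edge; the abutting gene starts
# exactly where region 2 ends and is therefore NOT reported (half-open).
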