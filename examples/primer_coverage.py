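"""In-silico coverage of the PolF primer against a synthetic reference set.

Plants binding sites with 0, 1 and 2 mismatches into simulated references
and tallies, per mismatch tier, how many strains and species the degenerate
primer would capture — the same nested-tier bookkeeping used to audit
published primer sets against a curated gene database.
"""

import numpy as np

from gtamp import DegeneratePrimer, POLF, expand_degenerate, probe_match
from gtamp.primers import TaxonLineage, bases_of
from gtamp.seqio import SequenceRecord

rng = np.random.default_rng(7)
pool = expand_degenerate(POLF)
print(f"PolF = {POLF}  ({len(pool)} concrete sequences in the pool)")

refs, taxonomy = [], {}
genera = ["Bradyrhizobium", "Azospirillum", "Geobacter"]
design = {0: 6, 1: 5, 2: 4, 3: 5}      # planted best-mismatch -> ref count
k = 0
for mm, count in design.items():
    for _ in range(count):
        site = list(pool[rng.integers(len(pool))])
        for p in rng.choice(len(site), size=mm, replace=False):
            outside = sorted(set("ACGT") - bases_of(POLF[p]))
            site[p] = outside[rng.integers(len(outside))]
        flank = lambda n: "".join("ACGT"[i] for i in rng.integers(4, size=n))
        refs.append(SequenceRecord(id=f"ref{k:02d}", seq=flank(40) + "".join(site) + flank(40)))
        taxonomy[f"ref{k:02d}"] = TaxonLineage(genus=genera[k % 3], species=f"sp{k}")
        k += 1

report = probe_match(DegeneratePrimer("PolF", POLF), refs, taxonomy, tiers=[0, 1, 2])
for t in (0, 1, 2):
    print(f"  <= {t} mismatches: {report.strain_counts[t]:2d} strains, "
          f"{report.species_counts[t]:2d} species")
# Tier counts are cumulative (0-mismatch hits are also 1- and 2-mismatch
# hits); references planted at 3 mismatches stay uncaptured at every tier.
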