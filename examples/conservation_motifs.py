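"""Positional conservation and motif prevalence in a protein family.

Builds an alignment of simulated family members around a planted
iron-binding-style motif (DX{2}HX{3,4}H) plus the NW(K/R) motif, profiles
per-column conservation and scans every sequence for the motifs.
"""

import numpy as np

from gtamp import compare_profiles, conservation_profile, motif_prevalence, motif_scan
from gtamp.seqio import SequenceRecord
from gtamp.simulate import _AA

rng = np.random.default_rng(5)
core = "DAAHAAAH"          # iron-binding style: D, X2, H, X3, H
nwk = "NWK"

seqs = []
for i in range(40):
    left = "".join(_AA[k] for k in rng.integers(20, size=10))
    right = "".join(_AA[k] for k in rng.integers(20, size=10))
    middle = core if i % 20 else "DAAHAAAA"   # 2 of 40 lose the second H
    tail = nwk if i % 10 else "NWR"           # K/R alternation
    seqs.append(SequenceRecord(id=f"env{i}", seq=left + middle + tail + right))

profile = conservation_profile(seqs, consensus_threshold=0.95)
motif_cols = range(10, 18)
print("column  consensus  %conserved   (motif region)")
for j in motif_cols:
    print(f"{j:6d}  {profile.consensus[j]:>9}  {profile.percent_conserved[j]:10.2f}")

iron = motif_prevalence(seqs, "DX{2}HX{3,4}H")
nw = motif_prevalence(seqs, "NW[KR]")
print(f"DX{{2}}HX{{3,4}}H prevalence: {iron:.1%} of sequences")
print(f"NW[KR] prevalence      : {nw:.1%} of sequences")
print(f"first hit span in env1 : {motif_scan(seqs[1], 'DX{2}HX{3,4}H')}")
# Both motifs exceed the 95% conservation criterion used to call a motif
# essential; the consensus letter drops to 'x' wherever conservation
# falls below the threshold.
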