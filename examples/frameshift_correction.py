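"""Correct a pyrosequencing-style frameshift and recover the protein.

Back-translates a reference protein, deletes one base mid-read (the classic
454 homopolymer error), and shows that the protein-guided aligner restores
the original translation while counting the frameshift event.
"""

import numpy as np

from gtamp import frameshift_align
from gtamp.framecorrect import translate_codon
from gtamp.simulate import _AA, _back_translate

rng = np.random.default_rng(11)
protein = "".join(_AA[k] for k in rng.integers(20, size=80))
dna = _back_translate(protein, rng)
damaged = dna[:100] + dna[101:]        # single-base deletion at base 100

# frame-0 naive translation of the damaged read for contrast
naive = "".join(
    translate_codon(damaged[i:i + 3]) for i in range(0, len(damaged) - 2, 3)
)
aln = frameshift_align(damaged, protein)

print(f"reference protein   : {protein[:40]}...")
print(f"naive translation   : {naive[:40]}...")
print(f"corrected protein   : {aln.protein[:40]}...")
print(f"frameshifts detected: {aln.n_frameshifts}")
print(f"identity to ref     : {aln.identity:.3f}")
print(f"restored exactly    : {aln.protein == protein}")
# The naive translation is garbage downstream of the deletion; the
# frameshift-aware path pays one penalty, resolves the missing base and
# reports 100% identity over the aligned columns.
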