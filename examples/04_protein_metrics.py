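"""Composition and isoelectric points of the five AMP families.

Percent K+R measures positively charged residues, percent Q+E the Glx
content; the pI is the pH at which the Henderson-Hasselbalch net charge of
the full precursor vanishes.  Defensins and drosomycins come out cationic
(pI > 7), termicins and blattellicins anionic (pI < 7).
"""

from collections import defaultdict

from amp_arsenal import synthetic_panel
from amp_arsenal.protein_metrics import composition, isoelectric_point

groups = defaultdict(list)
for gene, prot in synthetic_panel.panel_proteins().items():
    groups[gene.split("_g")[0]].append(prot)

print(f"{'family':<14} {'n':>2} {'%K+R':>6} {'%Q+E':>6} {'mean pI':>8}")
for fam, prots in groups.items():
    comp = composition(prots, fam)
    mean_pi = sum(isoelectric_point(p) for p in prots) / len(prots)
    print(f"{fam:<14} {len(prots):>2} {comp.pct_positive:>6.1f} "
          f"{comp.pct_glx:>6.1f} {mean_pi:>8.2f}")
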