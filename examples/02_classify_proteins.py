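"""Classify proteins into the five AMP classes from sequence architecture.

For one protein per family the script prints the predicted signal peptide,
the Glx-rich segment (blattellicins only), the best family-domain hit and
the resulting class label.  The Glx segment length > 70 combined with an
attacin domain and > 200 aa total is what defines a blattellicin.
"""

from amp_arsenal import synthetic_panel
from amp_arsenal.amp_classifier import annotate

profiles = synthetic_panel.panel_profiles()
proteins = synthetic_panel.panel_proteins()

for gene in ("defensin_g2", "termicin_g1", "drosomycin_g2",
             "attacin-like_g1", "blattellicin_g1"):
    prot = proteins[gene]
    ann = annotate(gene, prot, profiles)
    glx = (f"{ann.glx_region[0]}-{ann.glx_region[1]} "
           f"(density {ann.glx_region[2]:.2f})" if ann.glx_region else "-")
    dom = ann.family_domain
    print(f"{gene:<16} {len(prot):>3} aa  signal {ann.signal[0]}-{ann.signal[1]:<3} "
          f"glx {glx:<24} domain {dom[0]} ({dom[3]:.0f} bits)  -> {ann.class_label}")
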