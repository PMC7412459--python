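"""Predict a leaf's quasi-color (CMQ) from pigment meter readings.

The published 2-3-3 tanh network maps chlorophyll (SR-S = sqrt SPAD) and
anthocyanin (Lb-A = log2 ACI) levels to the midpoint quasi-color of the two
leaf surfaces.  The first case is the darkest leaf in the original survey
(mondo grass 'Nigrescens'); the second is lettuce sample LS-101.
"""

from cmqleaf import PigmentLevel, predict_cmq, published_cmq_network

net = published_cmq_network()

for label, srs, lba in [("mondo grass", 9.7, 7.5), ("lettuce LS-101", 5.4, 3.9)]:
    cmq = predict_cmq(net, PigmentLevel(srs, lba))
    print(
        f"{label:15s} SR-S={srs:4.1f} Lb-A={lba:4.1f} -> "
        f"qL*={cmq.qL:5.1f} qa*={cmq.qa:5.1f} qb*={cmq.qb:5.1f} "
        f"qC*={cmq.qC:5.1f} qh={cmq.qh('0-360'):5.1f} deg"
    )

# Low qL* means a dark quasi-color; near-zero qC* means it is almost
# achromatic — mondo grass leaves look nearly black because they are rich
# in both pigments at once.
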