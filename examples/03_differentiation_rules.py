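"""Walk through the mechano-regulation rule table on hand-picked stimuli.

Classifies strain states into differentiation events, applies the
associated tissue-fraction updates, and homogenizes the resulting element
material by the rule of mixtures.
"""

import numpy as np

from osteosim import Event, apply_event, classify_event, homogenize_material

pure_granulation = np.array([1.0, 0.0, 0.0, 0.0])

cases = [
    # (eps_H %, eps_d %, description)
    (6.0, 2.0, "excessive volumetric strain"),
    (2.0, 10.0, "moderate distortion"),
    (-2.0, 8.0, "compression + distortion"),
    (0.5, 0.5, "gentle stimulus near bone"),
    (0.0, 0.2, "near-zero stimulus (disuse)"),
]

comp = pure_granulation
for eH, ed, label in cases:
    event = classify_event(eH, ed, comp[None, :], neighbor_bone_ok=True)
    updated = apply_event(pure_granulation, event)
    E, nu = homogenize_material(updated)
    print(
        f"eps_H={eH:+5.1f}%  eps_d={ed:5.1f}%  ({label:32s}) -> "
        f"{Event(int(event)).name:15s} fractions={np.round(updated, 3)}  "
        f"E={E:8.4f} MPa"
    )

# Destruction resets an element to granulation tissue; fibrous/cartilage
# formation transfer volume out of granulation at their table rates;
# intramembranous ossification (low stimulus next to bone) deposits bone
# directly; near-zero stimulus resorbs existing bone.
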