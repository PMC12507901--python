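"""Classify mechanical stimuli into the bone-healing window.

The stimulus at a fracture-gap element is the pair (octahedral shear strain,
volumetric strain). The default window partitions that plane into
intramembranous ossification (low distortion, near-zero volume change),
endochondral ossification (moderate distortion under compression) and
connective tissue (everything else, unfavorable). The boundaries are
scientific inputs: edit the YAML this script writes and reload it.
"""

import numpy as np

import fractwin as fw

window = fw.default_window()
print("classes:", window.class_names)

stimuli = [
    (0.02, -0.001),   # gentle distortion, slight compression
    (0.10, -0.02),    # moderate distortion under compression
    (0.40, 0.0),      # severe distortion
    (0.01, 0.30),     # large volumetric expansion
]
for gamma, vol in stimuli:
    name = np.asarray(window.classify_names(gamma, vol)).item()
    tag = "favorable" if window.favorable[name] else "unfavorable"
    print(f"  gamma_oct={gamma:5.2f}, eps_vol={vol:6.3f} -> {name} ({tag})")

# Strain invariants from a full tensor:
E = np.array([[0.012, 0.002, 0.0], [0.002, -0.004, 0.0], [0.0, 0.0, -0.006]])
print(f"octahedral shear strain: {fw.octahedral_shear(E):.5f}")
print(f"volumetric strain:       {fw.volumetric_strain(E):+.5f}")

window.save("scratch_window.yaml")
print("window written to scratch_window.yaml (edit and reload with "
      "HealingWindowConfig.load)")
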