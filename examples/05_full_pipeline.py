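"""Full run: phantom -> calibration -> mesh -> FE -> assessment, three levels.

Compares 20 kg partial load, 50% body weight and full weight-bearing on the
same synthetic construct. Because the model is linear, the stiffness is
factorized once and each level only re-weights three unit-load solutions.
The verdicts below show the typical pattern: the implant stays below its
880 MPa yield at partial loads, while strain in the soft fracture gap grows
with the applied load.
"""

import fractwin as fw

config = fw.RunConfig(
    phantom=fw.PhantomSpec(shape=(24, 24, 48), spacing=2.5),
    patient_mass=70.0,
    seed=1,
    out_dir="scratch_run",
    write_fields=True,
)
result = fw.run(config)

print(f"mesh: {result.mesh.n_elements} tets | "
      f"calibration slope {result.calibration.slope:.4f} mg/cm3 per HU")
print(f"{'level':10s} {'peak |F| (N)':>12s} {'gap gamma_oct':>14s} "
      f"{'implant VM (MPa)':>17s} {'stable':>7s} {'healing':>8s}")
for level in config.levels:
    d = result.report["levels"][level.value]
    print(f"{level.value:10s} {d['peak_force_N']['magnitude']:12.1f} "
          f"{d['peak_gap_octahedral_shear_strain']:14.4f} "
          f"{d['peak_implant_von_mises_MPa']:17.1f} "
          f"{str(d['stable']):>7s} {str(d['healing_ok']):>8s}")
print("reports and VTU fields written to scratch_run/")
# Peak gap strain and implant stress grow monotonically with the applied
# load; 'stable' compares the peak implant von Mises stress with the 880 MPa
# yield strength of the titanium alloy.
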