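"""Build a reference knee-force database and scale it to a patient.

Knee joint forces are stored as %BW (percent body weight: 100 * F / (m*g)).
A cohort of synthetic two-peak stance curves is averaged per weight-bearing
level; substituting a patient means multiplying the level's mean curve by
the patient's body weight. An insole ground-reaction-force curve is checked
against the prescribed 20 kg partial load.
"""

import fractwin as fw

levels = [fw.WeightBearingLevel.PWB_20KG, fw.WeightBearingLevel.PWB_50PCT,
          fw.WeightBearingLevel.FULL]
curves = {
    level: [fw.generate_gait_curve(fw.SyntheticCurveSpec.for_level(level, seed=s, noise_sd=5.0))
            for s in range(22)]
    for level in levels
}
db = fw.build_reference(curves)

patient_mass = 70.0  # kg
for level in levels:
    peak_pct = db.mean[level].F[:, 2].max()
    lc = fw.scale_to_patient(db, level, patient_mass)
    print(f"{level.value:10s}: axial peak {peak_pct:6.1f} %BW "
          f"-> {lc.forces[:, 2].max():7.1f} N at {patient_mass:.0f} kg")
# Note the 20-kg level: a 20 kg partial load still drives the knee force to
# roughly one full body weight, which is why partial weight bearing does not
# proportionally unload the knee.

grf = fw.generate_insole_curve(196.2, fw.InsoleCurveSpec(rel_error_sd=0.05, seed=3))
report = fw.check_compliance(grf, prescribed_load=20.0)
print(f"insole peak {report.peak_N:.1f} N vs target {report.target_N:.1f} N "
      f"-> ratio {report.ratio:.2f}, verdict: {report.verdict}")
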