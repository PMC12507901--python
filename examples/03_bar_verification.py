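"""Analytic verification of the finite-element solver.

A 10 x 10 x 100 mm bar with E = 1000 MPa and nu = 0, fixed at the base and
loaded axially with 1000 N (consistent tributary-area distribution), has the
closed-form solution: tip displacement FL/EA = 1.000 mm and uniform axial
stress F/A = 10 MPa. Constant-strain tets represent this state exactly, so
the solver must reproduce it to machine precision.
"""

import numpy as np

import fractwin as fw
from fractwin.materials import ElementMaterials

mesh = fw.build_mesh(np.ones((2, 2, 20), dtype=int), 5.0, fw.MeshConfig(end_set_fraction=0.01))
mats = ElementMaterials(E=np.full(mesh.n_elements, 1000.0),
                        nu=np.zeros(mesh.n_elements), region=mesh.region)
load = fw.LoadCase(times=[1.0], forces=[[0.0, 0.0, 1000.0]])
res = fw.solve_static(mesh, mats, fw.BoundaryCondition(), load, distribution="area")

tip = res.displacement(0)[np.asarray(mesh.node_sets["proximal"]), 2]
stress = res.stress_voigt(0)
print(f"mesh: {mesh.n_elements} tets, {mesh.n_nodes} nodes")
print(f"tip displacement: {tip.mean():.12f} mm   (closed form: 1.000000000000)")
print(f"axial stress:     {stress[:, 2].mean():.12f} MPa (closed form: 10.000000000000)")
print(f"max |u_z - 1| = {np.abs(tip - 1).max():.2e}, "
      f"max |s_zz - 10| = {np.abs(stress[:, 2] - 10).max():.2e}")
print(f"reaction force:   {res.reaction_force(0)} N (balances the 1000 N load)")
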