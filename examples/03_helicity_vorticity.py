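"""Vorticity and local normalized helicity on two analytic flows.

Solid-body rotation has omega = 2 Omega along the axis and LNH = 0 (planar
vortex); an ABC (Beltrami) flow has velocity parallel to its own curl, so
LNH = 1 everywhere.
"""

import numpy as np

from hemomap.fields import VoxelVectorMap
from hemomap.helivort import compute_lnh, compute_vorticity

# --- solid-body rotation about z, Omega = 1 rad/s
n, sp = 16, 2.0
g = np.indices((n, n, n)).astype(float) * sp
c = (n - 1) * sp / 2
v = np.zeros((n, n, n, 3))
v[..., 0] = -(g[1] - c) * 0.1  # 0.1 cm/s per mm == 1 1/s in SI
v[..., 1] = (g[0] - c) * 0.1
vm = VoxelVectorMap(v, np.ones((n, n, n), bool), sp, np.zeros(3))
vort = compute_vorticity(vm)
lnh = compute_lnh(vm, vort)
print("solid-body rotation:")
print(f"  mean omega_z : {np.nanmean(vort.omega[vort.valid][:, 2]):.6f} 1/s (truth 2.0)")
print(f"  max |LNH|    : {np.nanmax(np.abs(lnh.lnh[lnh.defined])):.2e} (truth 0)")

# --- ABC flow: V is an eigenvector of curl -> LNH = 1
nn, period = 32, 40.0
h, k = period / nn, 2 * np.pi / period
X, Y, Z = np.indices((nn, nn, nn)).astype(float) * h
abc = np.stack(
    [np.sin(k * Z) + np.cos(k * Y),
     np.sin(k * X) + np.cos(k * Z),
     np.sin(k * Y) + np.cos(k * X)], axis=-1)
vm2 = VoxelVectorMap(abc, np.ones((nn, nn, nn), bool), h, np.zeros(3))
lnh2 = compute_lnh(vm2, compute_vorticity(vm2))
inner = np.zeros((nn, nn, nn), bool)
inner[4:-4, 4:-4, 4:-4] = True
print("ABC (Beltrami) flow:")
print(f"  min interior LNH : {np.nanmin(lnh2.lnh[lnh2.defined & inner]):.6f} (truth 1)")
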