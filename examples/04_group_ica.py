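"""Group spatial ICA on synthetic voxel mixtures with known sources.

Component time courses are mixed through localized spatial maps into voxel
data for several subjects; the two-stage decomposition (subject PCA, group
PCA, Infomax with ICASSO stability) recovers the maps, and GICA3
back-reconstruction returns per-subject time courses whose average map
equals the group map exactly.
"""

import warnings

import numpy as np

from dfnckit.groupica import gica3_backreconstruct, group_decompose, match_components
from dfnckit.synth import mix_to_voxels, random_mixing_maps

warnings.simplefilter("ignore")
rng = np.random.default_rng(5)
C, V, T, M = 6, 600, 200, 4

maps = random_mixing_maps(C, V, seed=1)
subjects = []
for _ in range(M):
    tc = rng.laplace(size=(T, C))
    subjects.append(mix_to_voxels(tc, maps, noise_sd=0.05, seed=rng).T)

res = group_decompose(subjects, n_subject_components=10,
                      n_group_components=C, n_runs=10, seed=0)
tcs, subj_maps = gica3_backreconstruct(res, subjects)
perm, signs, _ = match_components(res.group_maps, maps)

print("component |corr| with its planted map, ICASSO stability:")
for j in range(C):
    r = abs(np.corrcoef(maps[j], res.group_maps[perm[j]])[0, 1])
    print(f"  IC{j + 1}: |r| = {r:.3f}   Iq = {res.stability_index[j]:.2f}")
gica3_err = np.max(np.abs(np.mean(subj_maps, axis=0) - res.group_maps))
print(f"\nGICA3 identity |mean(subject maps) - group maps| = {gica3_err:.1e}")
print("All sources should match at |r| > 0.9; the GICA3 identity holds to")
print("numerical precision by construction of the back-reconstruction.")
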