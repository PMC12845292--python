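"""Physiology computations: fluorescence, chlorosis, metals, PCA, ANOSIM.

Generates noiseless physiology tables at the study's configured means and
a synthetic chlorotic leaf image, then prints every derived parameter.
"""

import numpy as np

from ferromir.datagen import (
    ImageSpec,
    SimConfig,
    default_fluorescence_specs,
    default_physio_specs,
    gen_leaf_image,
    gen_physio_table,
)
from ferromir.physio import (
    anosim,
    eigenvalue_from_fraction,
    fv_fm,
    hue_chlorosis,
    pca_correlation,
    percent_change,
    yield_ii,
)

# --- chlorophyll fluorescence
fl, _ = gen_physio_table(SimConfig(seed=1, physio_spec=default_fluorescence_specs()))
for trt in ("CK", "FeD", "RE"):
    row = fl[fl.treatment == trt].groupby("measure")["value"].mean()
    print(f"{trt}: Fv/Fm = {fv_fm(row['F0'], row['Fm']):.2f}, "
          f"Y(II) = {yield_ii(row['Fmp'], row['Fs']):.2f}")
# Deficiency drops Fv/Fm from 0.78 to 0.74; resupply recovers it to 0.76.

# --- metal content percent change
met, _ = gen_physio_table(SimConfig(seed=1, physio_spec=default_physio_specs()))
g = met.groupby(["tissue", "treatment", "measure"])["value"].mean()
print(f"root Fe change under deficiency: "
      f"{percent_change(g['root', 'CK', 'Fe'], g['root', 'FeD', 'Fe']):.0f}%")
print(f"leaf Fe change under deficiency: "
      f"{percent_change(g['leaf', 'CK', 'Fe'], g['leaf', 'FeD', 'Fe']):.0f}%")

# --- image-based chlorosis
img, _ = gen_leaf_image(
    SimConfig(image_spec=ImageSpec(foreground_hue=62.0, foreground_pixels=6000))
)
call = hue_chlorosis(img.rgb, reference_hue=120.0)
print(f"leaf hue {call.mean_hue:.1f} deg, shift {call.shift:.1f} deg "
      f"over {call.roi_pixels} px -> {call.verdict}")

# --- correlation PCA: eigenvalue/variance-fraction identity
print(f"a PC explaining 45.26% of 12 variables has eigenvalue "
      f"{eigenvalue_from_fraction(45.26, 12):.4f}")
rng = np.random.default_rng(0)
X = rng.normal(size=(24, 12)) @ rng.normal(size=(12, 12))
res = pca_correlation(X)
print(f"eigenvalue sum = {res.eigenvalues.sum():.6f} (equals n_variables = 12)")

# --- ANOSIM on clearly separated groups
d = np.array([[0, 1, 5, 6], [1, 0, 7, 8], [5, 7, 0, 2], [6, 8, 2, 0]], float)
r = anosim(distances=d, groups=["a", "a", "b", "b"])
print(f"ANOSIM R = {r.r:.2f}, exhaustive p = {r.p:.3f} over {r.n_permutations} labelings")
# R = 1 means every between-group distance outranks every within-group one.
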