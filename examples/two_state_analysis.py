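"""Two-state ensemble -> PCA -> order parameters -> alpha/beta fractions.

Builds a synthetic two-state domain ensemble (70% alpha, 0.3 A coordinate
noise), runs the full conformational-state analysis, and compares the
recovered state populations with the generator's ground truth.
"""

import numpy as np

import nsh2kit as nk
from nsh2kit.analysis import superpose

res = nk.build_two_state_ensemble(n_frames=2000, alpha_fraction=0.7,
                                  noise_sd=0.3, seed=7)
ens, rmsd = superpose(res.ensemble, res.alpha_reference, nk.core_fit_selection())
cv = nk.pca(ens, nk.analysis_selection())[0]
ops = nk.order_parameters(res.ensemble)
cls = nk.classify_states(ops)

print(f"core-fit RMSD (mean):      {rmsd.mean():.2f} A")
print(f"PC1 variance fraction:     {cv.variance_fraction:.2f}")
print(f"R(sheet, pY loop):         {nk.pearson(ops.sheet, ops.pY):+.2f}")
print(f"R(pY loop, +5 site):       {nk.pearson(ops.pY, ops.plus5):+.2f}")
frac, lo, hi = cls.fractions["alpha"]
print(f"alpha fraction:            {frac:.3f}  (95% CI {lo:.3f}-{hi:.3f})")
print(f"true alpha fraction:       {np.mean(res.labels == 'alpha'):.3f}")
print(f"label accuracy:            {np.mean(cls.labels == res.labels):.3f}")
print()
print("The negative sheet/pY and positive pY/+5 correlations are the")
print("allosteric coupling signature; the classifier recovers the generator's")
print("state populations from the three order-parameter distances alone.")
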