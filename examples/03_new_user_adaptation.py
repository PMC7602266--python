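"""Closed-form adaptation of a fitted bilinear model to an unseen user.

Fits a model, then synthesizes calibration data for a brand-new user from the
model's own interaction and motion factors with a known user factor z*. The
pseudo-inverse chain should recover z* and reconstruct the calibration data
essentially exactly; the projected motion factors for unlabeled data then
match the model's shared motion factors.
"""

import numpy as np

from emgsign import bilinear as bl
from emgsign.synthetic import BilinearGenConfig, generate_bilinear_instance

cfg = BilinearGenConfig(I=3, J=5, C=8, U=6, M=4, N=6, seed=21)
Y, *_ = generate_bilinear_instance(cfg)
model = bl.fit(Y, cfg.dims)

rng = np.random.default_rng(1)
z_star = rng.standard_normal(model.I)
response = bl.stacked_transpose(
    bl.StackedMatrix(bl.stacked_transpose(model.W).data @ z_star[:, None], model.dims["C"])
).data  # the new user's per-channel response, C x J
y_cal = bl.StackedMatrix(response @ model.motion_columns(0), model.dims["C"])

adapted = bl.adapt_new_user(model, y_cal, m=0)
print(f"calibration: motion 0, {y_cal.shape[1]} repetitions, {y_cal.block_count} channels")
print(f"reconstruction residual (relative): {adapted.residual_relative:.2e}")
print(f"user-factor recovery error: "
      f"{np.linalg.norm(adapted.z_new - z_star) / np.linalg.norm(z_star):.2e}")

y_all = bl.StackedMatrix(response @ model.X, model.dims["C"])
x_proj = bl.project_motions(adapted, y_all)
err = np.linalg.norm(x_proj - model.X) / np.linalg.norm(model.X)
print(f"projected motion factors vs model factors (relative error): {err:.2e}")
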