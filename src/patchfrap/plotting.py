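"""Minimal curve/fit overlay plot."""

from __future__ import annotations

import numpy as np

from .forward_model import BeamProtocol, MobilityParams, model_curve
from .fitting import FitResult, normalize_curve
from .synthetic import RecoveryCurve


def plot_fit(curve: RecoveryCurve, fit: FitResult, beam: BeamProtocol, ax=None):
    """Overlay a normalized recovery curve with its fitted diffusion model."""
    import matplotlib.pyplot as plt

    nc = normalize_curve(curve)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(nc.t, nc.F, ".", ms=3, color="0.5", label="data")
    if fit.converged:
        fitted_beam = beam.replace(K=fit.K_used, t_grid=nc.t_post)
        model = model_curve(fitted_beam, MobilityParams(D=fit.D_hat, R_f=fit.R_f_hat))
        ax.plot(nc.t_post, model, "-", color="C3",
                label=f"fit: $R_f$={fit.R_f_hat:.2f}, D={fit.D_hat * 100:.2f}e-2 µm²/s")
    ax.axvline(0.0, color="k", lw=0.5, ls=":")
    ax.set_xlabel("time after bleach (s)")
    ax.set_ylabel("F / F$_{pre}$")
    ax.set_title(curve.cell_id)
    ax.legend(frameon=False, fontsize=8)
    return ax
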