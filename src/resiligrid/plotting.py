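"""Optional plots of gradient profiles with fitted curves and 95% bands."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .gradient import BinnedProfile, GradientFit, select_fit

__all__ = ["plot_profiles"]


def plot_profiles(panels: dict[str, tuple[BinnedProfile, list[GradientFit] | None]],
                  path: str | Path) -> Path:
    """Panel grid of binned profiles (points) with the selected fit and its
    confidence band, one panel per response."""
    n = len(panels)
    ncols = 2 if n > 1 else 1
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(5.2 * ncols, 3.6 * nrows),
                             squeeze=False)
    for ax, (name, (profile, fits)) in zip(axes.ravel(), panels.items()):
        ax.errorbar(profile.bin_mid, profile.mean_y, yerr=profile.sd_y,
                    fmt="o", ms=4, capsize=2, color="k", lw=1)
        if fits:
            fit = select_fit(fits)
            ax.plot(fit.ci_x, fit.predict(fit.ci_x), "-", color="tab:blue",
                    label=f"{fit.family} (R$^2$={fit.r2:.2f})")
            ax.fill_between(fit.ci_x, fit.ci_lo, fit.ci_hi, alpha=0.25,
                            color="tab:blue")
            ax.legend(frameon=False, fontsize=8)
        ax.set_xlabel("MAP (mm)")
        ax.set_ylabel(name.replace("_", " "))
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
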