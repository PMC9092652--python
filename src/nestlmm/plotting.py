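"""Static plots: fitted trajectories and residual profiles.

matplotlib is imported lazily so the estimation stack works headless.
"""

from __future__ import annotations

from .model import LMMResults, predict_blup

__all__ = ["plot_fitted_lines", "plot_residual_profiles"]


def plot_fitted_lines(fit: LMMResults, level: str = "subject", ax=None):
    """Observed points plus fitted trajectories per unit at one level.

    ``level`` is ``"subject"`` (one line per mouse) or ``"cluster"`` (the
    fitted lines averaged within each donor).
    """
    import matplotlib.pyplot as plt

    _, df = predict_blup(fit)
    if level == "cluster" and "cluster" not in df.columns:
        raise ValueError("dataset has no cluster column")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    groups = sorted(df["group"].unique())
    colors = {g: c for g, c in zip(groups, ("C0", "C1"))}
    unit = "subject" if level == "subject" else "cluster"
    for uid, sub in df.groupby(unit, observed=True):
        sub = sub.sort_values("time")
        c = colors[sub["group"].iloc[0]]
        if level == "cluster":
            line = sub.groupby("time")["fitted"].mean()
            ax.plot(line.index, line.values, color=c, alpha=0.8)
        else:
            ax.plot(sub["time"], sub["fitted"], color=c, alpha=0.6)
        ax.scatter(sub["time"], sub["response"], s=6, color=c, alpha=0.3)
    for g in groups:
        ax.plot([], [], color=colors[g], label=str(g))
    ax.set_xlabel("time (days)")
    ax.set_ylabel("response")
    ax.set_title(f"Fitted trajectories by {unit}")
    ax.legend()
    return ax


def plot_residual_profiles(profiles, ax=None):
    """Per-subject conditional residual trendlines over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for _, sub in profiles.groupby("subject", observed=True):
        ax.plot(sub["time"], sub["resid"], color="gray", alpha=0.4, lw=0.8)
    ax.axhline(0.0, color="k", lw=1)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("conditional residual")
    ax.set_title("Residual profiles")
    return ax
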