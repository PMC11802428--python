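"""Small plotting helpers (tornado diagram, CEAC, survival curves)."""

from __future__ import annotations

import numpy as np


def plot_tornado(dsa_table, ax=None, top: int = 10):
    """Horizontal-bar tornado diagram from a run_dsa table."""
    import matplotlib.pyplot as plt

    df = dsa_table.dropna(subset=["nmb_swing"]).head(top).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.5 * len(df) + 1))
    base = df["nmb_low"].add(df["nmb_high"]).div(2).iloc[-1] if len(df) else 0.0
    for i, (_, row) in enumerate(df.iterrows()):
        lo, hi = sorted((row["nmb_low"], row["nmb_high"]))
        ax.barh(i, hi - lo, left=lo, height=0.6)
    ax.set_yticks(range(len(df)), df["parameter"])
    ax.axvline(base, color="k", lw=0.8)
    ax.set_xlabel("Net monetary benefit ($)")
    return ax


def plot_ceac(psa_results, ax=None):
    """Cost-effectiveness acceptability curve from run_psa results."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(psa_results.wtp_grid, psa_results.ceac)
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    return ax


def plot_curves(curves: dict, t_max: float = 120.0, ax=None):
    """Overlay survival curves; ``curves`` maps label -> SurvivalCurve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.linspace(0, t_max, 400)
    for label, curve in curves.items():
        ax.plot(t, curve.survival(t), label=label)
    ax.set_xlabel("Months")
    ax.set_ylabel("Survival")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
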