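"""Markdown tables and figures for pipeline results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .association import RegressionResult
from .lagged import LagRegressionResult, classify_effect_size

__all__ = ["regression_markdown", "lag_markdown", "plot_lag_coefficients"]

_LABELS = {
    "mean_rt": "Mean RT",
    "rt_adjustment": "Systematic RT adjustments",
    "log_resid_var": "Residual RT variability",
}


def regression_markdown(result: RegressionResult, title: str = "") -> str:
    lines = []
    if title:
        lines.append(f"### {title}")
    lines.append(f"Outcome: {result.outcome} — F({result.df_model}, "
                 f"{result.df_resid}) = {result.f_stat:.2f}, "
                 f"R² = {result.r2:.2f}, p = {result.f_pvalue:.3g}, n = {result.n}")
    lines.append("")
    lines.append("| RT component | β | t | p | effect size |")
    lines.append("|---|---|---|---|---|")
    for c, b in result.betas.items():
        lines.append(
            f"| {_LABELS.get(c, c)} | {b:.2f} | {result.tvalues[c]:.2f} | "
            f"{result.pvalues[c]:.3g} | {classify_effect_size(b)} |")
    return "\n".join(lines) + "\n"


def lag_markdown(result: LagRegressionResult, max_lags: dict[str, float]) -> str:
    lines = [f"### Lagged prediction of {result.outcome} "
             f"(n clusters = {result.n_clusters})", ""]
    header = "| Lag (years) | " + " | ".join(
        f"{_LABELS.get(c, c)} β (t) " for c in result.components) + "|"
    lines.append(header)
    lines.append("|" + "---|" * (len(result.components) + 1))
    for b in result.bins:
        cells = [f"{(b - 1) * 0.5:g}–{b * 0.5:g}"]
        for c in result.components:
            cells.append(f"{result.betas[c][b]:.2f} ({result.tvalues[c][b]:.2f})")
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    for c in result.components:
        lines.append(
            f"- {_LABELS.get(c, c)}: interaction "
            f"F{result.interaction_df[c]} = {result.interaction_F[c]:.2f} "
            f"(p = {result.interaction_p[c]:.3g}); max stable lag "
            f"{max_lags[c]:.1f} years")
    return "\n".join(lines) + "\n"


def plot_lag_coefficients(result: LagRegressionResult, path: str | Path) -> Path:
    """Coefficient-vs-lag figure with 95% CI error bars per component."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for c in result.components:
        xs = [result.bin_years[b] for b in result.bins]
        ys = [result.betas[c][b] for b in result.bins]
        lo = [ys[i] - result.ci_low[c][b] for i, b in enumerate(result.bins)]
        hi = [result.ci_high[c][b] - ys[i] for i, b in enumerate(result.bins)]
        ax.errorbar(xs, ys, yerr=[lo, hi], marker="o", capsize=2,
                    label=_LABELS.get(c, c))
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("Lag before cognitive test (years)")
    ax.set_ylabel("Standardized β")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
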