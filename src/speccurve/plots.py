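"""Specification-curve figures: curve + decision panel, per-choice box
plots, variance-share bars and the correlation heat map.

All functions are pure renderers of fitted results: they return the
matplotlib figure (and write PNG/SVG when given a path stem) without
mutating the inputs.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np               # noqa: E402

__all__ = [
    "plot_specification_curve",
    "plot_choice_boxplots",
    "plot_variance_shares",
    "plot_correlation_matrix",
]


def _decision_rows(ordered):
    """(label, x-positions) rows for the decision panel, one per level."""
    rows = []
    for cls in ("outcome", "predictor", "covariates", "outliers"):
        levels = list(dict.fromkeys(ordered[cls]))
        for lev in levels:
            xs = np.flatnonzero((ordered[cls] == lev).to_numpy())
            label = lev if len(str(lev)) <= 24 else str(lev)[:21] + "..."
            rows.append((f"{cls}: {label}", xs))
    return rows


def _save(fig, path_stem):
    if path_stem is not None:
        path_stem = str(path_stem)
        fig.savefig(path_stem + ".png", dpi=150)
        fig.savefig(path_stem + ".svg")


def plot_specification_curve(results, path_stem=None, max_panel_rows=40):
    """Two-panel curve figure.

    Top: each model's standardized coefficient with its 95% CI, sorted
    ascending, dashed line at the curve median.  Bottom: one row per
    decision level with ticks aligned to that level's models.
    """
    ordered = results.ordered()
    if len(ordered) == 0:
        raise ValueError("no results to plot")
    x = np.arange(len(ordered))
    rows = _decision_rows(ordered)
    if len(rows) > max_panel_rows:
        # collapse the covariate-set rows into none/single/all for legibility
        ordered = ordered.copy()
        nc = ordered["n_covariates"].map({0: "none", 16: "all"}).fillna(
            "single")
        ordered["covariates"] = nc
        rows = _decision_rows(ordered)

    fig, (ax, axp) = plt.subplots(
        2, 1, figsize=(11, 3.2 + 0.16 * len(rows)), sharex=True,
        gridspec_kw={"height_ratios": [3.0, 0.08 * len(rows) * 3]})
    ax.vlines(x, ordered["ci_low"], ordered["ci_high"],
              color="lightcoral", alpha=0.6, lw=0.8)
    ax.plot(x, ordered["beta"], ".", ms=2.5, color="darkred")
    med = float(ordered["beta"].median())
    ax.axhline(med, ls="--", color="black", lw=1)
    ax.axhline(0.0, ls=":", color="grey", lw=0.8)
    ax.set_ylabel("standardized coefficient")
    ax.set_title(f"specification curve ({len(ordered)} models; "
                 f"median = {med:.2f})")

    for i, (label, xs) in enumerate(rows):
        axp.plot(xs, np.full(xs.size, -i), "|", ms=4, color="darkred")
    axp.set_yticks([-i for i in range(len(rows))])
    axp.set_yticklabels([r[0] for r in rows], fontsize=6)
    axp.set_xlabel("models, ordered by effect size")
    axp.set_ylim(-len(rows) + 0.5, 0.5)
    fig.tight_layout()
    _save(fig, path_stem)
    return fig


def plot_choice_boxplots(results, path_stem=None):
    """Horizontal box plot of coefficients per decision level (1.5 IQR
    whiskers, fliers beyond), with the level median marked."""
    df = results.results
    if len(df) == 0:
        raise ValueError("no results to plot")
    groups, labels = [], []
    for cls in ("outcome", "predictor", "outliers"):
        for lev in dict.fromkeys(df[cls]):
            groups.append(df.loc[df[cls] == lev, "beta"].to_numpy())
            labels.append(f"{cls}: {lev}")
    nc = df["n_covariates"].map({0: "none", 16: "all"}).fillna("single")
    for lev in ("none", "single", "all"):
        sel = df.loc[(nc == lev).to_numpy(), "beta"].to_numpy()
        if sel.size:
            groups.append(sel)
            labels.append(f"covariates: {lev}")
    fig, ax = plt.subplots(figsize=(8, 0.32 * len(groups) + 1.5))
    ax.boxplot(groups, orientation="horizontal", tick_labels=labels,
               whis=1.5,
               flierprops={"marker": ".", "markerfacecolor": "red",
                           "markeredgecolor": "red", "markersize": 4},
               medianprops={"color": "black"})
    ax.tick_params(axis="y", labelsize=7)
    ax.set_xlabel("standardized coefficient")
    fig.tight_layout()
    _save(fig, path_stem)
    return fig


def plot_variance_shares(decomposition, path_stem=None,
                         comparison=None, labels=("full curve", "reduced")):
    """Bar chart of class-normalized variance shares (summing to 100%);
    optionally overlaid with a second decomposition for comparison."""
    classes = list(decomposition.shares)
    x = np.arange(len(classes))
    fig, ax = plt.subplots(figsize=(7, 4))
    width = 0.38 if comparison is not None else 0.6
    ax.bar(x - (width / 2 if comparison is not None else 0),
           [100 * decomposition.shares[c] for c in classes],
           width, label=labels[0], color="purple")
    if comparison is not None:
        ax.bar(x + width / 2, [100 * comparison.shares[c] for c in classes],
               width, label=labels[1], color="seagreen")
        ax.legend()
    ax.set_xticks(x)
    ax.set_xticklabels(classes)
    ax.set_ylabel("share of effect-size variance (%)")
    fig.tight_layout()
    _save(fig, path_stem)
    return fig


def plot_correlation_matrix(corr, path_stem=None):
    """Heat map of the zero-order correlation matrix."""
    fig, ax = plt.subplots(figsize=(0.32 * len(corr) + 2,) * 2)
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)))
    ax.set_xticklabels(corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr)))
    ax.set_yticklabels(corr.index, fontsize=6)
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    _save(fig, path_stem)
    return fig
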