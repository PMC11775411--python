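"""Domestic-prey reliance scores (PCA) and the diet-vs-disturbance models.

The presence matrix is collapsed to prey group x origin indicator columns
(e.g. ungulate_domestic, rodent_wild), PCA is run on their covariance
matrix (all indicators share the 0/1 scale, so no rescaling), and the
first principal component is taken as a per-scat reliance score. PC1 is
sign-oriented so that scats containing at least one domestic taxon score
higher on average than scats with none: positive = domestic-reliant.

Two linear-model contracts link the scores to their predictors:

* ``patch_predator``: PC1 ~ forest patch + predator species (multiple
  regression) plus a two-way ANOVA with the patch x predator interaction;
* ``disturbance``: PC1 ~ forest proportion within 1000 m + distance to
  forest edge + fragmentation level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm


def indicator_matrix(pm: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """0/1 scats x (group, origin) indicators pooled from the presence matrix."""
    missing = [t for t in pm.columns if t not in catalog.index]
    if missing:
        raise KeyError(f"taxa missing from catalog: {missing}")
    keys = [f"{catalog.at[t, 'group']}_{catalog.at[t, 'origin']}"
            for t in pm.columns]
    pooled = pm.T.groupby(pd.Index(keys)).any().T
    return pooled.astype(float)


def reliance_scores(
    pm: pd.DataFrame,
    catalog: pd.DataFrame,
    predictors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-scat PC1 reliance score, oriented so domestic-reliant > 0.

    Optional ``predictors`` (same index) are carried through to the model
    layer. Raises on a constant indicator matrix (no variance to summarize).
    """
    if len(pm) < 3:
        raise ValueError("need at least 3 scats for a PCA")
    x = indicator_matrix(pm, catalog)
    if np.allclose(x.to_numpy().var(axis=0), 0):
        raise ValueError("indicator matrix is constant; PCA undefined")
    pc1 = PCA(n_components=1).fit_transform(x.to_numpy())[:, 0]

    domestic_cols = [c for c in x.columns if c.endswith("_domestic")]
    has_domestic = (x[domestic_cols].sum(axis=1) > 0
                    if domestic_cols else pd.Series(False, index=x.index))
    if has_domestic.any() and (~has_domestic).any():
        if pc1[has_domestic.to_numpy()].mean() < pc1[~has_domestic.to_numpy()].mean():
            pc1 = -pc1
    out = pd.DataFrame({"pc1": pc1}, index=pm.index)
    if predictors is not None:
        out = out.join(predictors)
    return out


def fit_diet_models(
    scores: pd.DataFrame,
    models: tuple[str, ...] = ("patch_predator", "disturbance"),
) -> dict:
    """Fit the requested model contracts; report R2, F, df, p per model.

    ``patch_predator`` expects columns patch and predator and adds a
    type-II two-way ANOVA with interaction; ``disturbance`` expects
    forest_prop, edge_dist and frag_level.
    """
    report: dict[str, dict] = {}
    if "patch_predator" in models:
        fit = ols("pc1 ~ C(patch) + C(predator)", data=scores).fit()
        inter = ols("pc1 ~ C(patch) * C(predator)", data=scores).fit()
        anova = anova_lm(inter, typ=2)
        report["patch_predator"] = {
            "r_squared": float(fit.rsquared),
            "f_stat": float(fit.fvalue),
            "df": (int(fit.df_model), int(fit.df_resid)),
            "p_value": float(fit.f_pvalue),
            "params": fit.params.to_dict(),
            "conf_int": {k: list(v) for k, v in
                         fit.conf_int().T.to_dict("list").items()},
            "anova": {
                str(term): {
                    "F": _nan_to_none(row["F"]),
                    "df": float(row["df"]),
                    "p": _nan_to_none(row["PR(>F)"]),
                }
                for term, row in anova.iterrows()
            },
        }
    if "disturbance" in models:
        fit = ols("pc1 ~ forest_prop + edge_dist + C(frag_level)",
                  data=scores).fit()
        report["disturbance"] = {
            "r_squared": float(fit.rsquared),
            "f_stat": float(fit.fvalue),
            "df": (int(fit.df_model), int(fit.df_resid)),
            "p_value": float(fit.f_pvalue),
            "params": fit.params.to_dict(),
            "conf_int": {k: list(v) for k, v in
                         fit.conf_int().T.to_dict("list").items()},
        }
    return report


def _nan_to_none(v):
    return None if pd.isna(v) else float(v)


def plot_reliance_ci(scores: pd.DataFrame, path: str) -> None:
    """Mean PC1 with 95% CI per forest patch x predator (point-range plot)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grouped = scores.groupby(["patch", "predator"])["pc1"]
    summary = grouped.agg(["mean", "sem", "count"]).reset_index()
    summary["ci95"] = 1.96 * summary["sem"].fillna(0)
    fig, ax = plt.subplots(figsize=(7, 4))
    patches = sorted(summary["patch"].unique())
    xs = {p: i for i, p in enumerate(patches)}
    for k, (pred, grp) in enumerate(summary.groupby("predator")):
        x = [xs[p] + 0.12 * k for p in grp["patch"]]
        ax.errorbar(x, grp["mean"], yerr=grp["ci95"], fmt="o", capsize=4,
                    label=str(pred))
    ax.set_xticks(range(len(patches)), patches)
    ax.set_ylabel("domestic-prey reliance (PC1)")
    ax.set_xlabel("forest patch")
    ax.axhline(0, color="grey", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
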