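"""Report generation: CSV tables and diagnostic plots.

Tables mirror the standard presentation of these analyses (model-comparison
fit statistics, class profiles, state characterization, validity-by-trim);
plots cover the erratic-state occupancy curve, the change-point
distribution, post-change residuals, and corrected-vs-original abilities.
Plots are artifacts only — all downstream consumption reads the CSVs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .joint_state_model import JointModelPosterior, occupancy_curve
from .rasch_mixture import MixtureRaschFit, likelihood_ratio_test

__all__ = [
    "mixture_fit_table",
    "write_mixture_report",
    "plot_occupancy_curve",
    "plot_changepoint_distribution",
    "plot_post_change_residuals",
    "plot_corrected_vs_original",
]


def mixture_fit_table(fits: list[MixtureRaschFit]) -> pd.DataFrame:
    """Model-comparison table: class sizes, -2lnL, parameters, AIC, chi-square."""
    fits = sorted(fits, key=lambda f: f.n_classes)
    rows = []
    for prev, fit in zip([None] + fits[:-1], fits):
        chi2 = p = None
        if prev is not None:
            lrt = likelihood_ratio_test(prev, fit)
            chi2, p = lrt.statistic, lrt.p_value
        rows.append({
            "n_classes": fit.n_classes,
            "class_sizes": ", ".join(f"{w:.2f}" for w in fit.class_weights),
            "minus2_loglik": fit.minus2_loglik,
            "n_params": fit.n_params,
            "aic": fit.aic,
            "chi2_vs_previous": chi2,
            "p_value": p,
        })
    return pd.DataFrame(rows)


def write_mixture_report(fits: list[MixtureRaschFit], out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    table = mixture_fit_table(fits)
    paths["fit_table"] = out_dir / "mixture_fit_table.csv"
    table.to_csv(paths["fit_table"], index=False)
    for fit in fits:
        p = out_dir / f"memberships_{fit.n_classes}class.csv"
        pd.DataFrame(
            fit.memberships,
            columns=[f"class_{g + 1}" for g in range(fit.n_classes)],
        ).assign(hard=fit.hard_assignments + 1).to_csv(p, index=False)
        paths[f"memberships_{fit.n_classes}"] = p
    return paths


def _save(fig, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_occupancy_curve(posterior: JointModelPosterior, path: str | Path) -> Path:
    curve = occupancy_curve(posterior)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["position"], curve["prop_erratic"], marker="o", ms=3)
    ax.set_xlabel("Item position")
    ax.set_ylabel("Proportion in erratic state")
    ax.set_ylim(bottom=0)
    return _save(fig, Path(path))


def plot_changepoint_distribution(posterior: JointModelPosterior, path: str | Path) -> Path:
    k = posterior.changepoint_params().k
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(k, bins=np.arange(0.5, posterior.n_items + 1.5), edgecolor="white")
    ax.set_xlabel("Estimated change point k")
    ax.set_ylabel("Examinees")
    return _save(fig, Path(path))


def plot_post_change_residuals(
    posterior: JointModelPosterior, residual_matrix: np.ndarray, path: str | Path
) -> Path:
    """Histogram of RT residuals at positions after each person's change point."""
    k = posterior.changepoint_params().k
    pos = np.arange(1, posterior.n_items + 1)
    post = pos[None, :] > k[:, None]
    vals = np.asarray(residual_matrix)[post]
    vals = vals[~np.isnan(vals)]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(vals, bins=40, edgecolor="white")
    ax.set_xlabel("lnRT residual after change point")
    ax.set_ylabel("Responses")
    return _save(fig, Path(path))


def plot_corrected_vs_original(
    original: np.ndarray, corrected: np.ndarray, path: str | Path
) -> Path:
    fig, ax = plt.subplots(figsize=(5, 5))
    ok = ~(np.isnan(original) | np.isnan(corrected))
    ax.scatter(original[ok], corrected[ok], s=12, alpha=0.6)
    lims = [min(np.min(original[ok]), np.min(corrected[ok])),
            max(np.max(original[ok]), np.max(corrected[ok]))]
    ax.plot(lims, lims, color="gray", lw=1)
    ax.set_xlabel("Whole-test ability (EAP)")
    ax.set_ylabel("Corrected ability (EAP, trimmed)")
    return _save(fig, Path(path))
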