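"""Standardization and per-date PCA of the 13 LI-P variables.

Each sampling date's complete records form a matrix of 13 variables (yield,
solids, SCC, treatments and the nine fatty-acid variables) which is
standardized column-wise to mean 0 / sample SD 1 and decomposed by principal
components on the correlation matrix. Two plot families summarize a date:
record scores on PC1-PC2 colored by farm (management clustering) and
variable loadings (which traits co-occur).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .herd_model import (
    DATE_CODES,
    LIP_VARIABLES,
    HerdDataset,
    HerdError,
    filter_complete_records,
)

__all__ = [
    "OrdinationResult",
    "OrdinationError",
    "standardize",
    "pca",
    "ordination_report",
]

logger = logging.getLogger(__name__)


class OrdinationError(HerdError):
    """Ordination cannot proceed (degenerate or insufficient data)."""


@dataclass
class OrdinationResult:
    """Loadings, record scores and variance explained for one sampling date."""

    date_code: Optional[str]
    variables: tuple[str, ...]
    loadings: pd.DataFrame          # variables x components
    record_scores: pd.DataFrame     # records x components (+ cow_id/farm_id keys)
    variance_fraction: np.ndarray   # per component, sums to 1

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.variance_fraction * len(self.variables)


def standardize(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Center each column to mean 0 and scale to sample SD 1 (n-1 denominator)."""
    is_frame = isinstance(matrix, pd.DataFrame)
    x = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise OrdinationError("expected a 2-D records x variables matrix")
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        names = ([matrix.columns[i] for i in bad] if is_frame else bad.tolist())
        raise OrdinationError(f"constant column(s) cannot be standardized: {names}")
    z = (x - x.mean(axis=0)) / sd
    if is_frame:
        return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return z


def pca(matrix: pd.DataFrame | np.ndarray,
        date_code: Optional[str] = None,
        keys: Optional[pd.DataFrame] = None) -> OrdinationResult:
    """Principal components of a standardized records x variables matrix.

    Components are the eigenvectors of the correlation matrix ordered by
    decreasing eigenvalue; the variance fraction of component i is
    lambda_i / sum(lambda). The sign of each loading vector is fixed by
    making its largest-magnitude entry positive. ``keys`` (e.g. cow_id and
    farm_id columns) are carried alongside the record scores.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    x = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if x.shape[0] < 3:
        raise OrdinationError(f"PCA needs at least 3 records, got {x.shape[0]}")
    n, p = x.shape
    corr = x.T @ x / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(p):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = x @ eigvec
    comp_names = [f"PC{i + 1}" for i in range(p)]
    var_names = tuple(matrix.columns) if is_frame else tuple(f"v{i}" for i in range(p))
    loadings = pd.DataFrame(eigvec, index=var_names, columns=comp_names)
    score_df = pd.DataFrame(scores, columns=comp_names,
                            index=matrix.index if is_frame else None)
    if keys is not None:
        score_df = pd.concat([keys.reset_index(drop=True),
                              score_df.reset_index(drop=True)], axis=1)
    return OrdinationResult(
        date_code=date_code, variables=var_names, loadings=loadings,
        record_scores=score_df,
        variance_fraction=eigval / eigval.sum(),
    )


def _plot_date(result: OrdinationResult, outdir: Path, fmt: str = "png") -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    d = result.date_code or "all"
    pc1, pc2 = result.variance_fraction[0] * 100, result.variance_fraction[1] * 100

    fig, ax = plt.subplots(figsize=(6, 5))
    farms = result.record_scores["farm_id"]
    cmap = plt.get_cmap("tab20")
    for i, farm in enumerate(sorted(farms.unique())):
        sub = result.record_scores[farms == farm]
        ax.scatter(sub["PC1"], sub["PC2"], s=10, color=cmap(i % 20),
                   label=str(farm), alpha=0.7)
    ax.set_xlabel(f"PC1 ({pc1:.0f}%)")
    ax.set_ylabel(f"PC2 ({pc2:.0f}%)")
    ax.set_title(f"LI-P record scores, {d} (colored by farm)")
    ax.legend(title="Farm", fontsize=6, ncol=2)
    path = outdir / f"scores_{d}.{fmt}"
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    paths.append(path)

    fig, ax = plt.subplots(figsize=(6, 5))
    for var in result.variables:
        lx, ly = result.loadings.loc[var, "PC1"], result.loadings.loc[var, "PC2"]
        ax.annotate("", xy=(lx, ly), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:blue", lw=0.8))
        ax.text(lx * 1.05, ly * 1.05, var, fontsize=7)
    lim = float(np.abs(result.loadings[["PC1", "PC2"]].to_numpy()).max()) * 1.3
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"PC1 ({pc1:.0f}%)")
    ax.set_ylabel(f"PC2 ({pc2:.0f}%)")
    ax.set_title(f"LI-P variable loadings, {d}")
    path = outdir / f"loadings_{d}.{fmt}"
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    paths.append(path)
    return paths


def ordination_report(
    dataset: HerdDataset,
    outdir: Optional[str | Path] = None,
    treatments_as: Literal["count", "indicator"] = "count",
) -> dict[str, OrdinationResult]:
    """Per-date standardized PCA of the complete records.

    For each sampling date with at least 3 complete records, standardizes the
    13 LI-P variables, runs PCA and (when ``outdir`` is given) writes a
    farm-colored score scatter, a loading plot and a ``variance.tsv`` table
    of PC1/PC2 variance fractions. Dates with fewer than 3 records are
    skipped with a logged warning. ``treatments_as`` selects whether the
    treatment variable enters as the raw count or the binary untreated
    indicator.
    """
    results: dict[str, OrdinationResult] = {}
    rows = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for date in DATE_CODES:
        sub = filter_complete_records(dataset, date)
        if len(sub) < 3:
            logger.warning("date %s has %d complete records; skipping ordination",
                           date, len(sub))
            continue
        df = sub.to_frame()
        mat = df[list(LIP_VARIABLES)].copy()
        if treatments_as == "indicator":
            mat["treatments_n"] = (mat["treatments_n"] == 0).astype(float)
        z = standardize(mat)
        res = pca(z, date_code=date, keys=df[["cow_id", "farm_id"]])
        results[date] = res
        rows.append({"date_code": date,
                     "PC1_frac": res.variance_fraction[0],
                     "PC2_frac": res.variance_fraction[1]})
        if out is not None:
            _plot_date(res, out)
    if out is not None and rows:
        pd.DataFrame(rows).to_csv(out / "variance.tsv", sep="\t", index=False,
                                  float_format="%.6g")
    return results
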