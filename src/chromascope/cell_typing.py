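"""Immunofluorescence gating and PBMC subset calling.

For each patient sample and surface marker, the area-normalized summed
marker intensities of all its cells are modelled as a two-component
univariate Gaussian mixture; the gate threshold is the equal-posterior
crossing point between the two component means, and the higher-mean
component is the marker-positive population. Per-sample fitting absorbs
staining-batch intensity differences. Cells strictly above the threshold
are positive; a value exactly at the threshold is negative (deterministic
tie rule). CD4/CD8 combinations define the subset label; CD3 status is
carried separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

__all__ = [
    "GateError",
    "MarkerGate",
    "CellTypeCall",
    "fit_marker_gate",
    "call_cell_types",
    "subset_abundance",
    "SUBSET_LABELS",
]

SUBSET_LABELS = ("CD4+CD8-", "CD4-CD8+", "CD4+CD8+", "CD4-CD8-")

#: gates whose component means are closer than this (in units of the larger
#: component SD) are flagged unreliable and excluded from typing
MIN_SEPARATION = 0.5


class GateError(ValueError):
    """Raised when a reliable positive/negative gate cannot be fitted."""


@dataclass(frozen=True)
class MarkerGate:
    sample_id: str
    marker: str
    means: tuple[float, float]  # (negative, positive), sorted ascending
    sds: tuple[float, float]
    weights: tuple[float, float]
    threshold: float
    converged: bool
    separation: float

    @property
    def reliable(self) -> bool:
        return self.converged and self.separation >= MIN_SEPARATION

    def is_positive(self, value) -> np.ndarray:
        return np.asarray(value) > self.threshold


@dataclass(frozen=True)
class CellTypeCall:
    nucleus_id: str
    cd3: bool | None
    cd4: bool | None
    cd8: bool | None
    subset: str
    partial: bool = False


def _equal_posterior_threshold(means, sds, weights) -> float:
    """Point between the component means where posterior responsibilities
    are equal, i.e. w1 N(x|m1,s1) = w2 N(x|m2,s2)."""

    def f(x):
        return (np.log(weights[0]) + norm.logpdf(x, means[0], sds[0])) - (
            np.log(weights[1]) + norm.logpdf(x, means[1], sds[1])
        )

    lo, hi = means
    flo, fhi = f(lo), f(hi)
    if flo > 0 and fhi < 0:
        return float(brentq(f, lo, hi))
    # pathological weights/variances: fall back to the variance-weighted
    # midpoint, still strictly between the means
    return float((means[0] * sds[1] + means[1] * sds[0]) / (sds[0] + sds[1]))


def fit_marker_gate(
    values: np.ndarray,
    sample_id: str = "",
    marker: str = "",
    min_cells: int = 20,
    seed: int = 0,
) -> MarkerGate:
    """Fit a per-sample two-component Gaussian mixture gate.

    Requires at least ``min_cells`` observations. Raises :class:`GateError`
    for degenerate inputs, non-convergence, or component separation
    |m2 - m1| / max(s1, s2) below ``MIN_SEPARATION``.
    """
    values = np.asarray(values, float).ravel()
    if values.size < min_cells:
        raise GateError(f"{sample_id}/{marker}: need >= {min_cells} cells, got {values.size}")
    if np.ptp(values) == 0:
        raise GateError(f"{sample_id}/{marker}: degenerate constant intensities")
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=10,
        tol=1e-6,
        max_iter=500,
        init_params="k-means++",
        random_state=seed,
        reg_covar=1e-10 * float(np.var(values) + 1e-30),
    ).fit(values[:, None])
    order = np.argsort(gmm.means_.ravel())
    means = tuple(float(m) for m in gmm.means_.ravel()[order])
    sds = tuple(float(np.sqrt(v)) for v in gmm.covariances_.ravel()[order])
    weights = tuple(float(w) for w in gmm.weights_[order])
    separation = (means[1] - means[0]) / max(sds)
    gate = MarkerGate(
        sample_id=sample_id,
        marker=marker,
        means=means,
        sds=sds,
        weights=weights,
        threshold=_equal_posterior_threshold(means, sds, weights),
        converged=bool(gmm.converged_),
        separation=float(separation),
    )
    if not gate.reliable:
        raise GateError(
            f"{sample_id}/{marker}: unreliable gate (converged={gate.converged}, "
            f"separation={separation:.2f} < {MIN_SEPARATION})"
        )
    return gate


def call_cell_types(gates: dict[str, MarkerGate], quants: pd.DataFrame) -> list[CellTypeCall]:
    """Assign per-cell marker positivity and the PBMC subset label.

    ``quants`` has one row per nucleus with columns ``nucleus_id`` plus the
    area-normalized intensity per marker (column = marker name). A missing
    marker or gate makes the call partial; the subset label then carries a
    '?' for the unknown axis.
    """
    calls = []
    for _, row in quants.iterrows():
        flags: dict[str, bool | None] = {}
        for m in ("CD3", "CD4", "CD8"):
            if m in gates and m in row.index and pd.notna(row[m]):
                flags[m] = bool(gates[m].is_positive(row[m]))
            else:
                flags[m] = None
        partial = flags["CD4"] is None or flags["CD8"] is None
        if partial:
            subset = "partial"
        else:
            subset = f"CD4{'+' if flags['CD4'] else '-'}CD8{'+' if flags['CD8'] else '-'}"
        calls.append(
            CellTypeCall(
                nucleus_id=str(row["nucleus_id"]),
                cd3=flags["CD3"],
                cd4=flags["CD4"],
                cd8=flags["CD8"],
                subset=subset,
                partial=partial or flags["CD3"] is None,
            )
        )
    return calls


def calls_table(calls: list[CellTypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nucleus_id": [c.nucleus_id for c in calls],
            "CD3": [c.cd3 for c in calls],
            "CD4": [c.cd4 for c in calls],
            "CD8": [c.cd8 for c in calls],
            "subset": [c.subset for c in calls],
            "partial": [c.partial for c in calls],
        }
    )


def subset_abundance(calls: pd.DataFrame, group_col: str | None = None) -> pd.DataFrame:
    """Relative abundance of the four CD4/CD8 subsets per sample.

    ``calls`` needs columns ``sample_id`` and ``subset``. Per-sample
    fractions sum to 1 over the four subsets. If ``group_col`` is given,
    group means and SDs across samples are appended as extra rows
    (statistic = 'mean'/'sd').
    """
    df = calls[calls["subset"].isin(SUBSET_LABELS)]
    if df.empty:
        raise ValueError("no typed cells")
    counts = (
        df.groupby("sample_id")["subset"].value_counts().unstack(fill_value=0).reindex(columns=SUBSET_LABELS, fill_value=0)
    )
    frac = counts.div(counts.sum(axis=1), axis=0)
    frac.insert(0, "statistic", "fraction")
    if group_col is not None:
        meta = calls.drop_duplicates("sample_id").set_index("sample_id")[group_col]
        frac[group_col] = meta.reindex(frac.index)
        rows = []
        for g, sub in frac.groupby(group_col):
            vals = sub[list(SUBSET_LABELS)]
            rows.append({group_col: g, "statistic": "mean", **vals.mean().to_dict()})
            rows.append({group_col: g, "statistic": "sd", **vals.std(ddof=1).to_dict()})
        frac = pd.concat([frac.reset_index(), pd.DataFrame(rows)], ignore_index=True)
    else:
        frac = frac.reset_index()
    return frac
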