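"""Component hotspots in 1-Mb windows and genomic-feature regression.

Hard-assigned singletons are pooled across the individuals of an ancestry
group and counted in non-overlapping 1-Mb windows.  A window is a hotspot
for (group, component) when its count lies strictly above the genome-wide
empirical 95th percentile for that stratum.  Per-window counts are related
to genomic covariates (histone marks, exon density, recombination rate,
...) by negative binomial regression with a log link,
log mu_w = beta_0 + sum_m beta_m X_{m,w}, variance mu + mu^2 / size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .intervals import overlap_length


@dataclass
class NBFit:
    beta: pd.Series          # named coefficients, intercept first
    se: pd.Series
    dispersion: float        # NB size; variance = mu + mu^2/size
    loglik: float
    converged: bool
    dropped: list[str]       # collinear feature columns removed before fitting


def make_windows(chrom_lengths: dict[str, int], window_size: int = 1_000_000
                 ) -> pd.DataFrame:
    """Tile each chromosome with [start, end) windows anchored at 0."""
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, int(length), window_size):
            rows.append((chrom, start, min(start + window_size, int(length))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def bin_component_counts(positions: pd.DataFrame,
                         chrom_lengths: dict[str, int],
                         window_size: int = 1_000_000) -> pd.DataFrame:
    """Count component-assigned singletons per (group, component, window).

    ``positions`` needs columns group, component, chrom, pos (0-based).
    Every declared window appears in the output, zeros included, so that
    hotspot percentiles are taken genome-wide and not just over occupied
    windows.
    """
    windows = make_windows(chrom_lengths, window_size)
    for chrom, sub in positions.groupby("chrom", sort=False):
        if chrom not in chrom_lengths:
            raise ValueError(f"chromosome {chrom} has no declared length")
        bad = sub["pos"].to_numpy()
        if (bad >= chrom_lengths[chrom]).any() or (bad < 0).any():
            raise ValueError(f"position beyond declared length of {chrom}")
    pos = positions.copy()
    pos["window"] = pos["pos"].to_numpy() // window_size
    grouped = (pos.groupby(["group", "component", "chrom", "window"])
               .size().rename("count").reset_index())
    grouped["start"] = grouped["window"] * window_size

    out = []
    for (group, component), sub in grouped.groupby(["group", "component"]):
        w = windows.copy()
        w["group"], w["component"] = group, component
        w = w.merge(sub[["chrom", "start", "count"]], on=["chrom", "start"],
                    how="left")
        w["count"] = w["count"].fillna(0).astype(np.int64)
        out.append(w)
    if not out:  # no singletons at all: zero table over one pseudo-stratum
        w = windows.copy()
        w["group"], w["component"], w["count"] = pd.NA, pd.NA, 0
        out.append(w)
    return pd.concat(out, ignore_index=True)[
        ["group", "component", "chrom", "start", "end", "count"]
    ]


def attach_features(table: pd.DataFrame, tracks: dict[str, pd.DataFrame]
                    ) -> pd.DataFrame:
    """Attach per-window mean feature signal from bedGraph-style tracks.

    Each track is a DataFrame (chrom, start, end, value); the window value
    is the base-weighted mean of overlapping track intervals over the
    window length.  Windows with no track coverage get NaN.
    """
    table = table.copy()
    for name, track in tracks.items():
        values = np.full(len(table), np.nan)
        for chrom, sub in track.groupby("chrom", sort=False):
            iv = sub[["start", "end"]].to_numpy(dtype=np.int64)
            val = sub["value"].to_numpy(dtype=float)
            sel = np.where((table["chrom"] == chrom).to_numpy())[0]
            for i in sel:
                w0, w1 = table["start"].iat[i], table["end"].iat[i]
                lo = np.maximum(iv[:, 0], w0)
                hi = np.minimum(iv[:, 1], w1)
                ov = np.maximum(hi - lo, 0)
                if ov.sum() > 0:
                    values[i] = float((ov * val).sum() / (w1 - w0))
        table[name] = values
    return table


def call_hotspots(table: pd.DataFrame, group, component,
                  quantile: float = 0.95) -> pd.DataFrame:
    """Flag windows strictly above the genome-wide count percentile.

    Returns the (group, component) slice of the table with a boolean
    ``hotspot`` column.  Ties at the threshold are not hotspots, so a
    constant count vector yields none.
    """
    sub = table[(table["group"] == group)
                & (table["component"] == component)].copy()
    if len(sub) < 20:
        raise ValueError(
            f"only {len(sub)} windows for ({group}, {component}); "
            "a percentile over fewer than 20 windows is not meaningful"
        )
    threshold = float(np.quantile(sub["count"].to_numpy(), quantile))
    sub["hotspot"] = sub["count"].to_numpy() > threshold
    return sub


def fit_nb_regression(table: pd.DataFrame, group, component,
                      features: list[str]) -> NBFit:
    """Negative binomial ML fit of window counts on feature means.

    Windows with any missing feature are dropped listwise.  Collinear
    feature columns are removed (QR pivot on the standardized design) with
    a warning before fitting.
    """
    sub = table[(table["group"] == group)
                & (table["component"] == component)]
    sub = sub.dropna(subset=features)
    y = sub["count"].to_numpy(dtype=float)
    X = sub[features].to_numpy(dtype=float)

    dropped: list[str] = []
    keep = _independent_columns(X)
    if len(keep) < X.shape[1]:
        dropped = [features[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping collinear features: {dropped}", stacklevel=2)
        X = X[:, keep]
    names = ["intercept"] + [features[j] for j in keep]
    design = sm.add_constant(X, has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, design)
        res = model.fit(disp=0, maxiter=200)
    converged = bool(res.mle_retvals.get("converged", True))
    params = pd.Series(res.params[:-1], index=names)
    se = pd.Series(res.bse[:-1], index=names)
    alpha = float(res.params[-1])  # statsmodels NB2 overdispersion
    size = 1.0 / alpha if alpha > 0 else np.inf
    return NBFit(params, se, size, float(res.llf), converged, dropped)


def _independent_columns(X: np.ndarray) -> list[int]:
    """Indices of a maximal linearly independent, non-constant column set."""
    keep: list[int] = []
    basis = np.ones((X.shape[0], 1)) / np.sqrt(X.shape[0])  # intercept span
    for j in range(X.shape[1]):
        col = X[:, j:j + 1].astype(float)
        resid = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(resid)
        if norm > 1e-8 * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            basis = np.hstack([basis, resid / norm])
    return keep
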