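"""Between-library regression normalization of miRNA expression.

Two libraries sequenced to different depths are made comparable by an
ordinary least-squares fit of library-B expression on library-A expression
over the matures detected in both, on a log10 scale by default (raw-scale
fitting is available but rarely sensible for count data spanning orders of
magnitude).  The fitted model is then applied per miRNA:
``x -> 10^(slope * log10(x) + intercept)``.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class NormalizationModel:
    slope: float
    intercept: float
    r_squared: float
    post_slope: float  # slope of the identity check after applying the model
    n_points: int
    scale: str = "log10"


def _as_series(expr) -> pd.Series:
    if isinstance(expr, pd.DataFrame):
        return expr.set_index("mature_id")["expression"]
    if isinstance(expr, pd.Series):
        return expr
    return pd.Series(dict(expr), dtype=float)


def fit_normalization(expr_a, expr_b, *, scale: str = "log10") -> NormalizationModel:
    """Fit the between-library OLS model on shared expressed matures.

    ``expr_a``/``expr_b`` may be mappings of mature_id to expression, pandas
    Series, or the DataFrames produced by ``expression_table``.  Matures with
    zero expression in either library are excluded (log undefined; no
    pseudocounts).  Requires at least 3 shared expressed matures.
    """
    if scale not in ("log10", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    a = _as_series(expr_a)
    b = _as_series(expr_b)
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared].astype(float), b.loc[shared].astype(float)
    mask = (a > 0) & (b > 0)
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError(f"need >=3 matures expressed in both libraries, got {len(a)}")
    if scale == "log10":
        x, y = np.log10(a.to_numpy()), np.log10(b.to_numpy())
    else:
        x, y = a.to_numpy(), b.to_numpy()
    fit = stats.linregress(x, y)
    # identity check: refit after applying the model to the fitting data
    x_norm = fit.slope * x + fit.intercept
    post = stats.linregress(x_norm, y) if np.ptp(x_norm) > 0 else None
    post_slope = float(post.slope) if post is not None else float("nan")
    r2 = float(fit.rvalue**2)
    if r2 >= 0.8 and not (0.9 <= post_slope <= 1.1):
        logger.warning(
            "post-normalization identity slope %.4f outside [0.9, 1.1]", post_slope
        )
    return NormalizationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        post_slope=post_slope,
        n_points=int(len(a)),
        scale=scale,
    )


def apply_normalization(model: NormalizationModel, expr) -> pd.Series:
    """Apply a fitted model; zero expression maps to zero."""
    s = _as_series(expr).astype(float)
    vals = s.to_numpy(copy=True)
    pos = vals > 0
    if model.scale == "log10":
        vals[pos] = 10.0 ** (model.slope * np.log10(vals[pos]) + model.intercept)
    else:
        vals[pos] = model.slope * vals[pos] + model.intercept
    vals[~pos] = 0.0
    return pd.Series(vals, index=s.index)


def save_model(model: NormalizationModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in ("slope", "intercept", "r_squared", "post_slope", "n_points", "scale"):
            fh.write(f"{key}\t{getattr(model, key)}\n")


def load_model(path: str | Path) -> NormalizationModel:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            key, _, value = line.rstrip("\n").partition("\t")
            kv[key] = value
    return NormalizationModel(
        slope=float(kv["slope"]),
        intercept=float(kv["intercept"]),
        r_squared=float(kv["r_squared"]),
        post_slope=float(kv["post_slope"]),
        n_points=int(kv["n_points"]),
        scale=kv.get("scale", "log10"),
    )
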