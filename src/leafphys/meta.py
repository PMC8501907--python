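"""Batch fitting, output compilation and local sensitivity analysis.

These meta-functions take fitting functions as arguments, so any
single-curve fitter in the package — or a user-supplied callable with the
same ``fit(data, **kwargs) -> result`` contract — scales to grouped data
sets (:func:`fit_many`), tabular summaries (:func:`compile_data`) and one-
or two-factor local sensitivity analyses over assumed inputs
(:func:`analyze_sensitivity` + :func:`compute_sensitivity`).

Two local sensitivity measures are computed against a user-defined
reference point p_ref, for a fitted output m:

    parameter effect     PE(p) = (m(p) - m(p_ref)) / m(p_ref)
    control coefficient  CE(p) = PE(p) / ((p - p_ref) / p_ref)

CE is the finite-difference relative elasticity; it tends to the analytic
elasticity d ln m / d ln p as the grid step shrinks.  On a two-factor grid
CE for one factor is defined along the axis where the other factor sits at
its reference value (and is NaN elsewhere), so axis slices of a two-factor
run reproduce the corresponding one-factor runs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult

__all__ = ["GroupedFits", "fit_many", "compile_data",
           "analyze_sensitivity", "compute_sensitivity"]


@dataclass
class GroupedFits:
    """Per-group fit results with failure isolation."""
    group_by: list[str]
    fits: dict = field(default_factory=dict)      # group key -> result
    failures: dict = field(default_factory=dict)  # group key -> error message

    def __len__(self) -> int:
        return len(self.fits) + len(self.failures)


def fit_many(
    data: pd.DataFrame,
    group_by: str | Sequence[str],
    fit_fn: Callable,
    **fit_args,
) -> GroupedFits:
    """Apply ``fit_fn`` independently to each group of ``data``.

    A failing group is logged in ``failures`` and does not abort the others.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    group_by = list(group_by)
    missing = [c for c in group_by if c not in data.columns]
    if missing:
        raise ValueError(f"grouping column(s) not in data: {', '.join(missing)}")
    grouped = data.groupby(group_by, sort=True, dropna=False)
    if grouped.ngroups == 0:
        raise ValueError("no groups to fit")
    out = GroupedFits(group_by=group_by)
    for key, grp in grouped:
        if len(group_by) == 1 and isinstance(key, tuple):
            key = key[0]
        try:
            out.fits[key] = fit_fn(grp.reset_index(drop=True), **fit_args)
        except Exception as exc:  # noqa: BLE001 - failure isolation is the contract
            out.failures[key] = f"{type(exc).__name__}: {exc}"
    return out


_SELECTORS = ("parameters", "fitted", "graphs")


def _result_params(result) -> dict:
    """Parameter dict from any supported result object."""
    if isinstance(result, FitResult):
        d = dict(result.params)
        d.update({f"{k}_se": v for k, v in result.se.items()})
        d["ssr"] = result.ssr
        d["aic"] = result.aic
        return d
    if isinstance(result, dict):  # e.g. a {model: FitResult} collection
        out = {}
        for name, r in result.items():
            for k, v in _result_params(r).items():
                out[f"{name}_{k}"] = v
        return out
    if hasattr(result, "to_dict"):
        return {k: v for k, v in result.to_dict().items()
                if isinstance(v, (int, float)) or v is None}
    raise TypeError(f"cannot extract parameters from {type(result)}")


def compile_data(fits: GroupedFits, selector: str = "parameters"):
    """Compile grouped fit output into one table (or object list) per group.

    ``selector``: ``"parameters"`` -> one-row-per-group DataFrame;
    ``"fitted"`` -> long DataFrame of fitted values and residuals;
    ``"graphs"`` -> dict of group key -> Figure for :func:`print_graphs`.
    """
    if selector not in _SELECTORS:
        raise ValueError(f"unknown selector {selector!r}; options: {', '.join(_SELECTORS)}")
    keys = list(fits.fits)
    if selector == "graphs":
        return {k: fits.fits[k].plot() for k in keys}
    rows = []
    for k in keys:
        tag = dict(zip(fits.group_by, k if isinstance(k, tuple) else (k,)))
        r = fits.fits[k]
        if selector == "parameters":
            rows.append({**tag, **_result_params(r)})
        else:
            if not isinstance(r, FitResult) or r.fitted is None:
                continue
            for i, (f, e) in enumerate(zip(r.fitted, r.residuals)):
                rows.append({**tag, "index": i, "fitted": float(f), "residual": float(e)})
    return pd.DataFrame(rows)


def analyze_sensitivity(
    fit_fn: Callable,
    data: pd.DataFrame,
    factor1: tuple[str, Sequence[float]],
    factor2: tuple[str, Sequence[float]] | None = None,
    *,
    outputs: Sequence[str] | None = None,
    arg_builder: Callable[[Mapping[str, float]], Mapping] | None = None,
    **fit_args,
) -> pd.DataFrame:
    """Re-run ``fit_fn`` over a grid of <= 2 assumed-input factors.

    Each factor is ``(argument_name, values)``; the argument must be
    accepted by ``fit_fn`` (or be translated by ``arg_builder``, which maps
    the factor-value dict to keyword arguments — useful when assumed inputs
    live inside a nested ``kinetics`` mapping).  Fitted outputs (all numeric
    parameters, or the subset in ``outputs``) are recorded per grid point;
    failures are flagged rows.
    """
    factors = [factor1] + ([factor2] if factor2 is not None else [])
    if len(factors) > 2:
        raise ValueError("at most two factors are supported")
    names = [f[0] for f in factors]
    grids = [list(f[1]) for f in factors]
    if any(len(g) == 0 for g in grids):
        raise ValueError("each factor needs at least one value")
    rows = []
    import itertools

    for combo in itertools.product(*grids):
        point = dict(zip(names, combo))
        kwargs = dict(fit_args)
        kwargs.update(arg_builder(point) if arg_builder else point)
        row = dict(point)
        try:
            result = fit_fn(data, **kwargs)
            pvals = _result_params(result)
            if outputs is not None:
                pvals = {k: v for k, v in pvals.items() if k in outputs}
            row.update(pvals)
            row["failed"] = False
        except Exception as exc:  # noqa: BLE001
            row["failed"] = True
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["factors"] = names
    return table


def compute_sensitivity(
    table: pd.DataFrame,
    ref: Mapping[str, float],
    output: str,
) -> pd.DataFrame:
    """Add parameter-effect and control-coefficient columns to a grid table.

    ``ref`` gives the reference value of every varied factor; the reference
    row must be on the grid.  See the module docstring for the formulas.
    """
    factors = table.attrs.get("factors") or [c for c in ref if c in table.columns]
    missing = [f for f in factors if f not in ref]
    if missing:
        raise ValueError(f"reference value missing for factor(s): {', '.join(missing)}")
    mask = np.ones(len(table), dtype=bool)
    for f in factors:
        mask &= np.isclose(table[f].to_numpy(dtype=float), float(ref[f]))
    if mask.sum() != 1:
        raise ValueError(
            f"reference point {dict(ref)} matches {int(mask.sum())} grid rows; need exactly 1")
    m_ref = float(table.loc[mask, output].iloc[0])
    out = table.copy()
    out.attrs = dict(table.attrs)
    out["reference"] = mask
    m = out[output].to_numpy(dtype=float)
    if m_ref == 0.0:
        out["parameter_effect"] = np.nan
        out.attrs["warning"] = "reference output is zero; parameter effect undefined"
    else:
        out["parameter_effect"] = (m - m_ref) / m_ref
    for f in factors:
        p = out[f].to_numpy(dtype=float)
        p_ref = float(ref[f])
        others_at_ref = np.ones(len(out), dtype=bool)
        for g in factors:
            if g != f:
                others_at_ref &= np.isclose(out[g].to_numpy(dtype=float), float(ref[g]))
        rel = np.where(p_ref != 0.0, (p - p_ref) / p_ref, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            ce = out["parameter_effect"].to_numpy(dtype=float) / rel
        ce = np.where(others_at_ref & (np.abs(rel) > 0), ce, np.nan)
        col = f"control_coefficient_{f}" if len(factors) > 1 else "control_coefficient"
        out[col] = ce
    return out


def plot_sensitivity(table: pd.DataFrame, output: str):
    """Heat map (two factors) or line plot (one factor) of a fitted output."""
    import matplotlib.pyplot as plt

    factors = table.attrs.get("factors", [])
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    if len(factors) == 2:
        pivot = table.pivot_table(index=factors[1], columns=factors[0], values=output)
        im = ax.pcolormesh(pivot.columns.to_numpy(dtype=float),
                           pivot.index.to_numpy(dtype=float),
                           pivot.to_numpy(), shading="nearest")
        fig.colorbar(im, ax=ax, label=output)
        ax.set_xlabel(factors[0])
        ax.set_ylabel(factors[1])
    else:
        ax.plot(table[factors[0]], table[output], "ko-")
        ax.set_xlabel(factors[0])
        ax.set_ylabel(output)
    fig.tight_layout()
    return fig
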