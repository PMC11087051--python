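"""Four-parameter log-logistic dose-response fitting and the screening cascade.

The model is the LL.4 parameterization common in pharmacology::

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with lower asymptote ``c``, upper asymptote ``d``, Hill slope ``b`` and
EC50 ``e`` (molar). With this sign convention an *increasing*
(agonist) curve has negative ``b``; the reported ``hill_slope`` is |b|,
matching the positive slopes conventionally printed.

Fitting is multi-start nonlinear least squares over (b, c, d, log10 e):
the EC50 is initialized at the geometric mean of the tested concentrations
and at each tested concentration, the slope at {0.5, 1, 2} of either sign,
with early stopping once a start explains the data essentially perfectly.
Any parameter subset may be pinned via ``fixed_params`` (e.g. the lower
asymptote for constitutively active receptors).

The screening cascade (peptide mixes -> single peptides -> dose series) is
represented by ``screen_mixes`` (hit when the peak response clears the
buffer-control mean by ``k`` control standard deviations) and
``summarize_pairs`` (lowest EC50 per receptor, receptor count per peptide).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import gmean

__all__ = [
    "FourPLFit",
    "four_pl",
    "fit_4pl",
    "normalize_plate",
    "screen_mixes",
    "summarize_pairs",
]


def four_pl(x, b, c, d, e):
    """LL.4 mean response at concentration(s) x (molar)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be strictly positive")
    if e <= 0:
        raise ValueError("EC50 must be strictly positive")
    z = np.clip(b * (np.log(x) - np.log(e)), -500.0, 500.0)
    return c + (d - c) / (1.0 + np.exp(z))


@dataclass
class FourPLFit:
    """Fitted LL.4 parameters with diagnostics."""

    lower: float
    upper: float
    hill_slope: float  # |b|
    ec50: float
    residual_sse: float
    converged: bool
    b_signed: float = 0.0
    fixed_params: tuple[str, ...] = ()
    n_points: int = 0
    receptor_id: str = ""
    peptide_id: str = ""


_PARAMS = ("b", "c", "d", "e")


def _theta_to_params(theta, fixed):
    out = {}
    i = 0
    for name in _PARAMS:
        if name in fixed:
            out[name] = fixed[name]
        else:
            out[name] = 10.0 ** theta[i] if name == "e" else theta[i]
            i += 1
    return out


def fit_4pl(
    dataset: pd.DataFrame,
    fixed_params: dict[str, float] | None = None,
    max_starts: int | None = None,
) -> FourPLFit:
    """Least-squares LL.4 fit of one receptor-peptide series.

    ``dataset`` is long format with columns ``concentration_M`` and
    ``response`` (extra columns such as receptor/peptide/replicate are
    carried through to the result labels when present). Requires >= 4
    distinct concentrations. A fit that cannot produce a dynamic range
    clearly above the residual noise is flagged ``converged=False`` rather
    than silently returning numbers.
    """
    fixed = dict(fixed_params or {})
    x = np.asarray(dataset["concentration_M"], dtype=float)
    y = np.asarray(dataset["response"], dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct concentrations to fit")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.any(x <= 0):
        raise ValueError("concentrations must be strictly positive")

    ymin, ymax = float(y.min()), float(y.max())
    yspan = max(ymax - ymin, 1e-12)
    log_conc = np.log10(np.unique(x))
    le_lo, le_hi = log_conc.min() - 3.0, log_conc.max() + 3.0

    free = [p for p in _PARAMS if p not in fixed]
    lo = {"b": -50.0, "c": ymin - 2 * yspan, "d": ymin - 2 * yspan, "e": le_lo}
    hi = {"b": 50.0, "c": ymax + 2 * yspan, "d": ymax + 2 * yspan, "e": le_hi}

    def residuals(theta):
        p = _theta_to_params(theta, fixed)
        return four_pl(x, p["b"], p["c"], p["d"], p["e"]) - y

    # data-driven smart start: EC50 near the midpoint crossing; try the
    # slope sign suggested by the response-concentration trend first
    mid = (ymin + ymax) / 2.0
    order = np.argsort(x)
    crossing = x[order][np.argmin(np.abs(y[order] - mid))]
    e_starts = [float(crossing), float(gmean(np.unique(x)))] + list(np.unique(x))
    increasing = np.corrcoef(np.log(x), y)[0, 1] >= 0
    likely = -1.0 if increasing else 1.0  # LL.4: negative b = increasing
    b_starts = [likely * s for s in (1.0, 0.5, 2.0)] + [-likely * s for s in (1.0, 0.5, 2.0)]

    starts = []
    for e0 in e_starts:
        for b0 in b_starts:
            starts.append({"b": b0, "c": ymin, "d": ymax, "e": e0})
    if max_starts:
        starts = starts[:max_starts]

    # replicate pure error bounds the achievable SSE: once a start gets
    # within 10% of it, further starts cannot meaningfully improve
    sse_pe = 0.0
    for xv in np.unique(x):
        g = y[x == xv]
        if g.size > 1:
            sse_pe += float(np.sum((g - g.mean()) ** 2))
    best = None
    sse_floor = 1.1 * sse_pe + (1e-9 * yspan) ** 2 * y.size
    for s0 in starts:
        theta0 = [
            np.log10(np.clip(s0[p], 10.0 ** le_lo, 10.0 ** le_hi)) if p == "e" else s0[p]
            for p in free
        ]
        try:
            res = least_squares(
                residuals,
                theta0,
                bounds=([lo[p] for p in free], [hi[p] for p in free]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=2000,
            )
        except Exception:  # singular starts are simply skipped
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res)
        if sse <= sse_floor:
            break

    if best is None:
        raise RuntimeError("all optimizer starts failed")
    sse, res = best
    p = _theta_to_params(res.x, fixed)
    rmse = np.sqrt(sse / y.size)
    span_fitted = abs(p["d"] - p["c"])
    converged = bool(res.success) and span_fitted > max(4.0 * rmse, 1e-9 * max(1.0, abs(ymax)))

    sub = dataset.iloc[0]
    return FourPLFit(
        lower=min(p["c"], p["d"]),
        upper=max(p["c"], p["d"]),
        hill_slope=abs(p["b"]),
        ec50=p["e"],
        residual_sse=sse,
        converged=converged,
        b_signed=p["b"],
        fixed_params=tuple(sorted(fixed)),
        n_points=int(y.size),
        receptor_id=str(sub.get("receptor", "")),
        peptide_id=str(sub.get("peptide", "")),
    )


def normalize_plate(
    dataset: pd.DataFrame, method: str = "minmax", baseline: float | None = None
) -> pd.DataFrame:
    """Normalize responses per receptor-peptide series.

    ``minmax`` maps the observed min to 0 and max to 1. ``baseline_adjusted``
    first subtracts a supplied constitutive-activity floor (clipping at 0)
    before min-max scaling — used for receptors with strong base activation
    whose apparent lower asymptote sits far above zero. ``none`` returns a
    copy unchanged.
    """
    if dataset.empty:
        raise ValueError("empty dataset")
    if method == "none":
        return dataset.copy()
    if method not in ("minmax", "baseline_adjusted"):
        raise ValueError(f"unknown normalization {method!r}")
    out = dataset.copy()
    keys = [c for c in ("receptor", "peptide") if c in out.columns]

    def _norm(g):
        y = g["response"].to_numpy(dtype=float)
        if method == "baseline_adjusted":
            if baseline is None:
                raise ValueError("baseline_adjusted requires a baseline value")
            y = np.clip(y - baseline, 0.0, None)
        span = y.max() - y.min()
        if span <= 0:
            raise ValueError("zero dynamic range; cannot normalize")
        g = g.copy()
        g["response"] = (y - y.min()) / span
        return g

    if keys:
        out = out.groupby(keys, group_keys=False)[out.columns].apply(_norm)
    else:
        out = _norm(out)
    return out.reset_index(drop=True)


def screen_mixes(
    plate_matrix: pd.DataFrame,
    control_wells: pd.DataFrame,
    k: float = 3.0,
) -> pd.DataFrame:
    """First cascade stage: call receptor-mix hits against buffer controls.

    ``plate_matrix`` has columns (receptor, mix, response); ``control_wells``
    has (receptor, response). A combination is a hit when its peak response
    is >= control mean + k * control sd for that receptor. Hits drive the
    single-peptide deconvolution stage.
    """
    for col in ("receptor", "mix", "response"):
        if col not in plate_matrix.columns:
            raise ValueError(f"plate_matrix missing column {col!r}")
    if control_wells.empty:
        raise ValueError("missing control wells")
    ctrl = control_wells.groupby("receptor")["response"].agg(["mean", "std", "count"])
    ctrl["std"] = ctrl["std"].fillna(0.0)

    rows = []
    for (receptor, mix), g in plate_matrix.groupby(["receptor", "mix"]):
        if receptor not in ctrl.index:
            raise ValueError(f"no control wells for receptor {receptor!r}")
        mu, sd = ctrl.loc[receptor, "mean"], ctrl.loc[receptor, "std"]
        peak = float(g["response"].max())
        rows.append(
            dict(
                receptor=receptor,
                mix=mix,
                peak_response=peak,
                threshold=mu + k * sd,
                hit=peak >= mu + k * sd,
            )
        )
    return pd.DataFrame(rows).sort_values(["receptor", "mix"]).reset_index(drop=True)


def summarize_pairs(fits: list[FourPLFit] | pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summaries feeding the connectome stage.

    Returns ``{"pairs", "per_receptor", "per_peptide"}``: the full pair
    table, the lowest EC50 (and its ligand) per receptor, and the number of
    receptors each peptide activates.
    """
    if isinstance(fits, pd.DataFrame):
        pairs = fits.copy()
    else:
        pairs = pd.DataFrame(
            [
                dict(
                    receptor=f.receptor_id,
                    peptide=f.peptide_id,
                    ec50=f.ec50,
                    hill_slope=f.hill_slope,
                    converged=f.converged,
                )
                for f in fits
            ]
        )
    if pairs.empty:
        empty = pd.DataFrame()
        return {"pairs": empty, "per_receptor": empty, "per_peptide": empty}
    idx = pairs.groupby("receptor")["ec50"].idxmin()
    per_receptor = (
        pairs.loc[idx, ["receptor", "peptide", "ec50"]]
        .rename(columns={"peptide": "best_ligand", "ec50": "lowest_ec50"})
        .sort_values("receptor")
        .reset_index(drop=True)
    )
    per_peptide = (
        pairs.groupby("peptide")["receptor"]
        .nunique()
        .rename("n_receptors")
        .reset_index()
        .sort_values("peptide")
        .reset_index(drop=True)
    )
    return {"pairs": pairs, "per_receptor": per_receptor, "per_peptide": per_peptide}
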