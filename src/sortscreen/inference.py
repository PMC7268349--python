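"""Guide-level inference of mean expression shifts from sorting-bin counts.

Each guide's cells are modeled as Normal(mu_g, 1) on the quantile-normalized
expression axis.  For a candidate shift mu, the expected fraction of a bin's
reads belonging to guide g is the guide's unsorted-library fraction scaled by
the ratio of shifted to unshifted bin occupancy:

    P_b(g | mu) = (r_0g / R_0) * S(b, mu) / S(b, 0)

Reads in each bin are treated as negative-binomially sampled: the guide's
count r_gb given the bin total R_b has log-mass

    log NB(r_gb; size=R_b, prob=1 - P_b(g|mu))

and mu_hat is the maximizer of the summed log-likelihood across bins.  A
pseudocount proportional to each bin's sequencing depth acts as a prior
favoring mu = 0 for poorly covered guides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .bins import SortingBin, occupancy, validate_bins

__all__ = [
    "GuideRecord",
    "Experiment",
    "nb_log_pmf",
    "expected_read_fraction",
    "estimate_guide_mu",
    "fit_guides",
    "guide_z_scores",
    "analyze_guides",
    "percent_of_normal_expression",
]

# Expected-fraction clipping keeps the NB log-mass finite when an extreme
# shift pushes a bin's expected occupancy ratio to the boundary.
_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-12


@dataclass
class GuideRecord:
    """A guide's annotations plus its read count per bin and unsorted."""

    guide_id: str
    counts: Mapping[str, int]
    unsorted_count: int
    is_negative_control: bool = False
    chrom: str | None = None
    pos: int | None = None  # 1-based
    element_label: str | None = None


@dataclass
class Experiment:
    """Bin definitions and per-bin read totals for one screen experiment."""

    experiment_id: str
    bins: list[SortingBin]
    bin_totals: Mapping[str, float]
    unsorted_total: float

    def __post_init__(self) -> None:
        validate_bins(self.bins)
        missing = [b.bin_id for b in self.bins if b.bin_id not in self.bin_totals]
        if missing:
            raise ValueError(f"bin totals missing for bins {missing}")


def nb_log_pmf(k, n, p_guide):
    """Log negative-binomial mass of observing ``k`` guide reads.

    Parameterized as in the read model: ``n`` total bin reads play the role of
    the NB "number of successes" and ``q = 1 - p_guide`` is the per-read
    probability of drawing some other guide, so

        log NB(k) = log C(k+n-1, k) + n log q + k log(1 - q)

    evaluated through log-gamma so non-integer (pseudocounted) ``k`` is
    supported.  Degenerate ``p_guide`` in {0, 1} yields ``-inf``.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p_guide, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            gammaln(k + n)
            - gammaln(n)
            - gammaln(k + 1.0)
            + n * np.log1p(-p)
            + k * np.log(p)
        )
    return np.where((p <= 0.0) | (p >= 1.0), -np.inf, out)


def expected_read_fraction(
    guide: GuideRecord, exp: Experiment, bin_id: str, mu: float
) -> float:
    """Expected fraction of bin ``bin_id``'s reads belonging to ``guide``.

    Returns ``(r_0g/R_0) * S(b, mu)/S(b, 0)``; at ``mu = 0`` this is simply
    the guide's share of the unsorted library.  A guide absent from the
    unsorted library has expected fraction 0 for every ``mu`` (it is
    unquantifiable).
    """
    if exp.unsorted_total <= 0:
        raise ValueError("unsorted library total must be positive")
    if guide.unsorted_count == 0:
        return 0.0
    b = next((x for x in exp.bins if x.bin_id == bin_id), None)
    if b is None:
        raise KeyError(f"unknown bin {bin_id!r}")
    lib_frac = guide.unsorted_count / exp.unsorted_total
    return float(lib_frac * occupancy(b.start_z, b.end_z, mu) / b.fraction)


def _loglik_profile(
    rp: np.ndarray,
    bin_totals: np.ndarray,
    lib_frac: np.ndarray,
    z0: np.ndarray,
    z1: np.ndarray,
    s0: np.ndarray,
    mu: np.ndarray,
) -> np.ndarray:
    """Summed NB log-likelihood over bins, up to mu-independent constants.

    ``rp``: pseudocounted counts (n_guides, n_bins); ``mu``: per-guide grids
    (n_guides, n_mu).  Only the ``R_b log(1-p) + r' log(p)`` terms depend on
    mu, so the combinatorial log-gamma terms are dropped; they cancel in the
    likelihood ratio and do not move the argmax.
    """
    s = norm.cdf(z1[None, None, :] - mu[:, :, None]) - norm.cdf(
        z0[None, None, :] - mu[:, :, None]
    )
    p = lib_frac[:, None, None] * s / s0[None, None, :]
    np.clip(p, _P_FLOOR, _P_CEIL, out=p)
    return (
        bin_totals[None, None, :] * np.log1p(-p) + rp[:, None, :] * np.log(p)
    ).sum(axis=2)


def _fit_mu_arrays(
    counts: np.ndarray,
    unsorted: np.ndarray,
    bin_totals: np.ndarray,
    unsorted_total: float,
    z0: np.ndarray,
    z1: np.ndarray,
    s0: np.ndarray,
    *,
    pseudocount_rate: float = 10.0,
    mu_bounds: tuple[float, float] = (-5.0, 5.0),
    tol: float = 1e-4,
    coarse_points: int = 201,
    block: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized MLE of mu for many guides: bracketing grid then refinement.

    A coarse grid over ``mu_bounds`` (always containing 0) brackets the
    optimum for each guide; the bracket is then re-gridded at 10x finer
    spacing until the spacing drops below ``tol``.  Returns (mu_hat,
    ll_ratio) with ll_ratio = max log-likelihood minus log-likelihood at 0.
    """
    lo, hi = float(mu_bounds[0]), float(mu_bounds[1])
    if not lo < 0.0 < hi:
        raise ValueError("mu search bounds must straddle 0")
    n_guides = counts.shape[0]
    pseudo = pseudocount_rate * bin_totals / 1e6
    rp = counts + pseudo[None, :]
    lib_frac = unsorted / unsorted_total

    grid = np.linspace(lo, hi, coarse_points)
    if not np.any(grid == 0.0):
        grid = np.sort(np.append(grid, 0.0))
    zero_idx = int(np.searchsorted(grid, 0.0))
    spacing = float(grid[1] - grid[0])

    mu_hat = np.zeros(n_guides)
    ll_ratio = np.zeros(n_guides)
    quantifiable = unsorted > 0
    idx_all = np.flatnonzero(quantifiable)

    for start in range(0, idx_all.size, block):
        sel = idx_all[start : start + block]
        rp_b, lf_b = rp[sel], lib_frac[sel]
        mus = np.broadcast_to(grid, (sel.size, grid.size))
        ll = _loglik_profile(rp_b, bin_totals, lf_b, z0, z1, s0, mus)
        ll0 = ll[:, zero_idx].copy()
        best = np.argmax(ll, axis=1)
        mu_b = grid[best]
        ll_b = ll[np.arange(sel.size), best]

        h = spacing
        while h > tol:
            local = mu_b[:, None] + np.linspace(-h, h, 21)[None, :]
            np.clip(local, lo, hi, out=local)
            ll = _loglik_profile(rp_b, bin_totals, lf_b, z0, z1, s0, local)
            best = np.argmax(ll, axis=1)
            mu_b = local[np.arange(sel.size), best]
            ll_b = ll[np.arange(sel.size), best]
            h /= 10.0

        mu_hat[sel] = mu_b
        ll_ratio[sel] = np.maximum(ll_b - ll0, 0.0)

    return mu_hat, ll_ratio


def estimate_guide_mu(
    guide: GuideRecord,
    exp: Experiment,
    *,
    pseudocount_rate: float = 10.0,
    search_bounds: tuple[float, float] = (-5.0, 5.0),
    tol: float = 1e-4,
) -> tuple[float, float]:
    """Maximum-likelihood mean shift for a single guide.

    Returns ``(mu_hat, ll_ratio)`` where ``ll_ratio`` is the log-likelihood at
    ``mu_hat`` minus that at ``mu = 0`` (natural log, always >= 0).  A guide
    with zero unsorted reads is unquantifiable and returns ``(0.0, 0.0)``.
    """
    bin_ids = [b.bin_id for b in exp.bins]
    counts = np.array([[float(guide.counts[b]) for b in bin_ids]])
    z0 = np.array([b.start_z for b in exp.bins])
    z1 = np.array([b.end_z for b in exp.bins])
    s0 = np.array([b.fraction for b in exp.bins])
    totals = np.array([float(exp.bin_totals[b]) for b in bin_ids])
    mu, llr = _fit_mu_arrays(
        counts,
        np.array([float(guide.unsorted_count)]),
        totals,
        float(exp.unsorted_total),
        z0,
        z1,
        s0,
        pseudocount_rate=pseudocount_rate,
        mu_bounds=search_bounds,
        tol=tol,
    )
    return float(mu[0]), float(llr[0])


def fit_guides(
    counts: pd.DataFrame,
    bins: Sequence[SortingBin],
    *,
    pseudocount_rate: float = 10.0,
    mu_bounds: tuple[float, float] = (-5.0, 5.0),
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Fit mu_hat for every guide of one experiment.

    ``counts`` must contain ``guide_id``, ``unsorted`` and one column per bin
    id; bin read totals are the column sums.  Returns a DataFrame with
    ``guide_id``, ``mu_hat``, ``ll_ratio`` and ``unquantifiable`` (True for
    guides absent from the unsorted library), preserving input row order.
    """
    validate_bins(bins)
    bin_ids = [b.bin_id for b in bins]
    missing = [b for b in bin_ids if b not in counts.columns]
    if missing:
        raise ValueError(f"count table lacks columns for bins {missing}")
    if "unsorted" not in counts.columns:
        raise ValueError(
            "count table lacks the required 'unsorted' column; the unsorted "
            "input library must be sequenced to quantify library composition"
        )
    mat = counts[bin_ids].to_numpy(dtype=float)
    unsorted = counts["unsorted"].to_numpy(dtype=float)
    bin_totals = mat.sum(axis=0)
    unsorted_total = float(unsorted.sum())
    if unsorted_total <= 0:
        raise ValueError("unsorted library has zero total reads")
    if np.any(bin_totals <= 0):
        empty = [bin_ids[i] for i in np.flatnonzero(bin_totals <= 0)]
        warnings.warn(f"bins with zero total reads: {empty}", stacklevel=2)
        bin_totals = np.maximum(bin_totals, 1e-9)

    z0 = np.array([b.start_z for b in bins])
    z1 = np.array([b.end_z for b in bins])
    s0 = np.array([b.fraction for b in bins])
    mu_hat, ll_ratio = _fit_mu_arrays(
        mat,
        unsorted,
        bin_totals,
        unsorted_total,
        z0,
        z1,
        s0,
        pseudocount_rate=pseudocount_rate,
        mu_bounds=mu_bounds,
        tol=tol,
    )
    return pd.DataFrame(
        {
            "guide_id": counts["guide_id"].to_numpy(),
            "mu_hat": mu_hat,
            "ll_ratio": ll_ratio,
            "unquantifiable": unsorted == 0,
        },
        index=counts.index,
    )


def guide_z_scores(
    results: pd.DataFrame,
    is_negative_control: np.ndarray | pd.Series,
    *,
    center: str = "mean",
) -> pd.DataFrame:
    """Convert fitted shifts to Z-scores anchored on negative controls.

    ``Z_g = mu_hat_g - center(mu_hat over negative controls)``, so the
    controls average exactly zero (with the default mean centering).  The
    median is available as an outlier-robust alternative.
    """
    ctrl = np.asarray(is_negative_control, dtype=bool)
    if ctrl.size != len(results):
        raise ValueError("control flag length does not match results")
    if not ctrl.any():
        raise ValueError(
            "no negative-control guides found: this analysis requires the "
            "screen to include negative control guides to anchor the null"
        )
    mu = results["mu_hat"].to_numpy(dtype=float)
    if center == "mean":
        offset = mu[ctrl].mean()
    elif center == "median":
        offset = float(np.median(mu[ctrl]))
    else:
        raise ValueError(f"unknown centering method {center!r}")
    out = results.copy()
    out["z_score"] = mu - offset
    return out


def analyze_guides(
    counts: pd.DataFrame,
    bins: Sequence[SortingBin] | Mapping[str, Sequence[SortingBin]],
    *,
    pseudocount_rate: float = 10.0,
    mu_bounds: tuple[float, float] = (-5.0, 5.0),
    tol: float = 1e-4,
    center: str = "mean",
) -> pd.DataFrame:
    """Full guide-level analysis, one or several experiments at once.

    If ``counts`` has an ``experiment_id`` column each experiment is fitted
    separately (``bins`` may be a mapping experiment_id -> bin list, or a
    single list shared by all).  Annotation columns (``is_negative_control``,
    ``chrom``, ``pos``, ``element_label``) are carried through to the output.
    """
    if "is_negative_control" not in counts.columns:
        raise ValueError("count table lacks 'is_negative_control' column")

    def bins_for(exp_id: str | None) -> Sequence[SortingBin]:
        if isinstance(bins, Mapping):
            key = exp_id if exp_id in bins else None
            if key not in bins:
                raise KeyError(f"no bin definitions for experiment {exp_id!r}")
            return bins[key]
        return bins

    carried = [
        c
        for c in ("is_negative_control", "chrom", "pos", "element_label")
        if c in counts.columns
    ]

    def one(exp_id: str | None, sub: pd.DataFrame) -> pd.DataFrame:
        fit = fit_guides(
            sub,
            bins_for(exp_id),
            pseudocount_rate=pseudocount_rate,
            mu_bounds=mu_bounds,
            tol=tol,
        )
        fit = guide_z_scores(fit, sub["is_negative_control"], center=center)
        fit.insert(1, "experiment_id", exp_id if exp_id is not None else "experiment")
        for c in carried:
            fit[c] = sub[c].to_numpy()
        return fit

    if "experiment_id" in counts.columns:
        parts = [
            one(exp_id, sub)
            for exp_id, sub in counts.groupby("experiment_id", sort=True)
        ]
        return pd.concat(parts, ignore_index=True)
    return one(None, counts).reset_index(drop=True)


def percent_of_normal_expression(
    z, sigma: float, mu_log: float, el_wt: float, el_null: float
):
    """Convert expression Z-scores to percent of wild-type expression.

    The sorting Z-score maps back to log-FACS space as ``x = sigma*z +
    mu_log``; the percentage is then ``100 * (10^x - 10^el_null) / (10^el_wt -
    10^el_null)``, where ``el_wt`` and ``el_null`` are the log-FACS mean
    expression of wild type and of a null mutant.  As ``el_null -> -inf`` this
    tends to ``100 * 10^(x - el_wt)``.
    """
    if not el_wt > el_null:
        raise ValueError("el_wt must exceed el_null for the scale to be defined")
    x = sigma * np.asarray(z, dtype=float) + mu_log
    if np.isneginf(el_null):
        return 100.0 * 10.0 ** (x - el_wt)
    return 100.0 * (10.0**x - 10.0**el_null) / (10.0**el_wt - 10.0**el_null)
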