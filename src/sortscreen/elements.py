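"""Element-level aggregation of guide Z-scores.

Guides targeting the same regulatory element are combined three ways: an
effect size (mean of guide Z-scores), a Stouffer Z (sum over sqrt(n)), and a
significance Z obtained by dividing the Stouffer Z by the standard deviation
of a matched null built from resampled negative-control guides.  The scaled
statistic is standard normal under no effect, so tail probabilities come from
the normal CDF and are BH-corrected per experiment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "NullModel",
    "stouffer_combine",
    "build_null_model",
    "element_significance",
    "annotated_elements",
    "sliding_window_elements",
    "bh_fdr",
    "combine_replicates",
]


def stouffer_combine(z_scores) -> float:
    """Stouffer combination of Z-scores: ``sum(z) / sqrt(n)``."""
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        raise ValueError("cannot Stouffer-combine an empty set of Z-scores")
    return float(z.sum() / np.sqrt(z.size))


@dataclass
class NullModel:
    """Null Stouffer-Z standard deviations from resampled control guides.

    ``sd_by_k`` maps a guide count k to the standard deviation of Stouffer
    Z-scores of k control Z-scores drawn without replacement from the pool in
    which every negative-control guide appears ``resample_factor`` times.
    """

    experiment_id: str | None
    sd_by_k: dict[int, float]
    resample_factor: int = 10
    n_draws: int = 10000
    seed: int = 0

    def sd(self, k: int) -> float:
        try:
            return self.sd_by_k[k]
        except KeyError:
            raise KeyError(
                f"null model has no entry for elements with {k} guides"
            ) from None


def _null_stouffer_draws(
    pool: np.ndarray, k: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Stouffer Z of ``n_draws`` without-replacement samples of size k.

    For k much smaller than the pool, index tuples are drawn with replacement
    and rows containing duplicates are redrawn (rejection sampling of distinct
    tuples, which is exactly uniform over without-replacement samples).  When
    k is a substantial fraction of the pool, the random-key trick is used
    instead: the k smallest of uniform keys over pool positions form a
    uniform without-replacement sample.
    """
    n = pool.size
    if k * k <= n:  # expected duplicate rate <= ~50%
        idx = rng.integers(0, n, size=(n_draws, k))
        bad = np.flatnonzero(
            (np.sort(idx, axis=1)[:, 1:] == np.sort(idx, axis=1)[:, :-1]).any(axis=1)
        )
        while bad.size:
            idx[bad] = rng.integers(0, n, size=(bad.size, k))
            srt = np.sort(idx[bad], axis=1)
            bad = bad[(srt[:, 1:] == srt[:, :-1]).any(axis=1)]
        return pool[idx].sum(axis=1) / np.sqrt(k)
    out = np.empty(n_draws)
    chunk = max(1, int(5e6 // n))
    for start in range(0, n_draws, chunk):
        m = min(chunk, n_draws - start)
        keys = rng.random((m, n))
        sel = np.argpartition(keys, k - 1, axis=1)[:, :k]
        out[start : start + m] = pool[sel].sum(axis=1) / np.sqrt(k)
    return out


def build_null_model(
    control_z,
    k_values: Iterable[int],
    *,
    resample_factor: int = 10,
    n_draws: int = 10000,
    seed: int = 0,
    experiment_id: str | None = None,
) -> NullModel:
    """Estimate null Stouffer-Z standard deviations for each guide count.

    Each negative-control Z-score is replicated ``resample_factor`` times to
    form a pool; for every requested k, ``n_draws`` sets of k values are drawn
    without replacement, Stouffer-combined, and their SD recorded.
    """
    z = np.sort(np.asarray(control_z, dtype=float))  # order-invariant pool
    if z.size < 2:
        raise ValueError("need at least 2 negative-control guides to build a null")
    k_values = sorted({int(k) for k in k_values})
    if not k_values:
        raise ValueError("no guide counts requested for the null model")
    pool = np.repeat(z, resample_factor)
    if max(k_values) > pool.size:
        raise ValueError(
            f"cannot draw {max(k_values)} control Z-scores without replacement "
            f"from a pool of {pool.size}; include more negative control guides "
            f"or raise resample_factor"
        )
    rng = np.random.default_rng(seed)
    sd_by_k: dict[int, float] = {}
    for k in k_values:
        draws = _null_stouffer_draws(pool, k, n_draws, rng)
        sd = float(draws.std(ddof=1))
        if sd <= 1e-12 * max(1.0, float(np.abs(draws).max())):
            raise ValueError(
                f"degenerate null for k={k}: resampled Stouffer Z-scores have "
                f"zero variance (controls identical, or k exhausts the pool)"
            )
        sd_by_k[k] = sd
    return NullModel(
        experiment_id=experiment_id,
        sd_by_k=sd_by_k,
        resample_factor=resample_factor,
        n_draws=n_draws,
        seed=seed,
    )


def element_significance(z_scores, null: NullModel) -> dict[str, float]:
    """Score one element from its member guide Z-scores.

    Returns the effect size (mean Z), Stouffer Z, null-scaled significance Z,
    and one-tailed / two-tailed ("either") p-values.  ``p_either`` doubles the
    smaller tail (capped at 1) so it is a valid p-value; the raw minimum is
    kept as ``p_min`` for diagnostics.
    """
    z = np.asarray(z_scores, dtype=float)
    stouffer = stouffer_combine(z)
    sig = stouffer / null.sd(z.size)
    p_up = float(norm.sf(sig))
    p_down = float(norm.cdf(sig))
    p_min = min(p_up, p_down)
    return {
        "n_guides": int(z.size),
        "effect_z": float(z.mean()),
        "stouffer_z": stouffer,
        "significance_z": float(sig),
        "p_up": p_up,
        "p_down": p_down,
        "p_min": p_min,
        "p_either": min(1.0, 2.0 * p_min),
    }


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


_FDR_TAILS = (("p_up", "fdr_up"), ("p_down", "fdr_down"), ("p_either", "fdr_either"))


def _attach_fdr(df: pd.DataFrame) -> pd.DataFrame:
    """BH-adjust each tail family separately within each experiment."""
    for p_col, q_col in _FDR_TAILS:
        df[q_col] = np.nan
    for _, idx in df.groupby("experiment_id", sort=False).groups.items():
        for p_col, q_col in _FDR_TAILS:
            df.loc[idx, q_col] = bh_fdr(df.loc[idx, p_col].to_numpy())
    return df


def _require_columns(df: pd.DataFrame, cols: Sequence[str], ctx: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{ctx}: missing required columns {missing}")


def _nulls_per_experiment(
    guide_results: pd.DataFrame,
    k_values_by_exp: Mapping[str, set[int]],
    null_model: NullModel | Mapping[str, NullModel] | None,
    resample_factor: int,
    n_draws: int,
    seed: int,
) -> dict[str, NullModel]:
    out: dict[str, NullModel] = {}
    for exp_id, ks in k_values_by_exp.items():
        if isinstance(null_model, NullModel):
            out[exp_id] = null_model
        elif isinstance(null_model, Mapping):
            out[exp_id] = null_model[exp_id]
        else:
            sub = guide_results[guide_results["experiment_id"] == exp_id]
            ctrl = sub.loc[
                sub["is_negative_control"].astype(bool), "z_score"
            ].to_numpy()
            out[exp_id] = build_null_model(
                ctrl,
                ks,
                resample_factor=resample_factor,
                n_draws=n_draws,
                seed=seed,
                experiment_id=exp_id,
            )
    return out


def annotated_elements(
    guide_results: pd.DataFrame,
    *,
    min_guides: int = 5,
    null_model: NullModel | Mapping[str, NullModel] | None = None,
    resample_factor: int = 10,
    n_draws: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Element statistics grouped by an a-priori element annotation.

    One row per (element_label, experiment) with at least ``min_guides``
    member guides; smaller elements are dropped with a logged warning.
    Negative-control guides and guides without a label are not assigned to
    elements (controls feed the null model instead).
    """
    _require_columns(
        guide_results,
        ["experiment_id", "z_score", "is_negative_control", "element_label"],
        "annotated_elements",
    )
    members = guide_results[
        ~guide_results["is_negative_control"].astype(bool)
        & guide_results["element_label"].notna()
    ]
    groups: list[tuple[str, str, np.ndarray]] = []
    for (exp_id, label), sub in members.groupby(
        ["experiment_id", "element_label"], sort=True
    ):
        z = sub["z_score"].to_numpy(dtype=float)
        if z.size < min_guides:
            logger.warning(
                "element %r in experiment %r has %d guides (< %d); excluded",
                label,
                exp_id,
                z.size,
                min_guides,
            )
            continue
        groups.append((exp_id, label, z))
    if not groups:
        return _empty_element_frame(with_coords=False)

    k_by_exp: dict[str, set[int]] = {}
    for exp_id, _, z in groups:
        k_by_exp.setdefault(exp_id, set()).add(z.size)
    nulls = _nulls_per_experiment(
        guide_results, k_by_exp, null_model, resample_factor, n_draws, seed
    )
    rows = []
    for exp_id, label, z in groups:
        row = {"element_id": label, "experiment_id": exp_id}
        row.update(element_significance(z, nulls[exp_id]))
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["experiment_id", "element_id"], ignore_index=True
    )
    return _attach_fdr(df)


def _enumerate_windows(
    pos: np.ndarray, guide_ids: np.ndarray, window_bp: int, min_guides: int
) -> list[np.ndarray]:
    """Distinct guide sets of width-``window_bp`` windows anchored at guides.

    Positions are sorted; every window is [anchor, anchor + window_bp) with
    the anchor at a guide position, which enumerates every distinct guide set
    a continuously sliding window can produce.  Sets are deduplicated by their
    frozen guide-ID set.
    """
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    seen: set[frozenset] = set()
    out: list[np.ndarray] = []
    for i in range(pos.size):
        # guides at the anchor's own position may sort before index i
        i0 = int(np.searchsorted(pos, pos[i], side="left"))
        j = int(np.searchsorted(pos, pos[i] + window_bp, side="left"))
        members = order[i0:j]
        if members.size < min_guides:
            continue
        key = frozenset(guide_ids[members])
        if key in seen:
            continue
        seen.add(key)
        out.append(members)
    return out


def sliding_window_elements(
    guide_results: pd.DataFrame,
    *,
    window_bp: int = 500,
    min_guides: int = 5,
    null_model: NullModel | Mapping[str, NullModel] | None = None,
    resample_factor: int = 10,
    n_draws: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score de-novo elements from tiled guides with a sliding window.

    For each chromosome and experiment, all windows of width ``window_bp``
    with distinct guide sets of at least ``min_guides`` members are scored.
    Reported element coordinates span the min to max member guide position
    (the window grid itself is arbitrary).
    """
    _require_columns(
        guide_results,
        ["experiment_id", "z_score", "is_negative_control", "guide_id"],
        "sliding_window_elements",
    )
    if "chrom" not in guide_results.columns or "pos" not in guide_results.columns:
        raise ValueError(
            "sliding-window mode needs 'chrom' and 'pos' guide annotations; "
            "for screens without genomic tiling use annotated-element mode "
            "(element_label column)"
        )
    targeting = guide_results[
        ~guide_results["is_negative_control"].astype(bool)
        & guide_results["chrom"].notna()
        & guide_results["pos"].notna()
    ]
    groups: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    for (exp_id, chrom), sub in targeting.groupby(
        ["experiment_id", "chrom"], sort=True
    ):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        ids = sub["guide_id"].to_numpy()
        z = sub["z_score"].to_numpy(dtype=float)
        for members in _enumerate_windows(pos, ids, window_bp, min_guides):
            groups.append((exp_id, chrom, pos[members], z[members]))
    if not groups:
        return _empty_element_frame(with_coords=True)

    k_by_exp: dict[str, set[int]] = {}
    for exp_id, _, _, z in groups:
        k_by_exp.setdefault(exp_id, set()).add(z.size)
    nulls = _nulls_per_experiment(
        guide_results, k_by_exp, null_model, resample_factor, n_draws, seed
    )
    rows = []
    for exp_id, chrom, p, z in groups:
        start, end = int(p.min()), int(p.max())
        row = {
            "element_id": f"{chrom}:{start}-{end}",
            "chrom": chrom,
            "start": start,
            "end": end,
            "experiment_id": exp_id,
        }
        row.update(element_significance(z, nulls[exp_id]))
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["experiment_id", "chrom", "start", "end", "n_guides"], ignore_index=True
    )
    return _attach_fdr(df)


def _empty_element_frame(with_coords: bool) -> pd.DataFrame:
    cols = ["element_id"]
    if with_coords:
        cols += ["chrom", "start", "end"]
    cols += [
        "experiment_id",
        "n_guides",
        "effect_z",
        "stouffer_z",
        "significance_z",
        "p_up",
        "p_down",
        "p_min",
        "p_either",
        "fdr_up",
        "fdr_down",
        "fdr_either",
    ]
    return pd.DataFrame(columns=cols)


def combine_replicates(
    element_results: pd.DataFrame,
    *,
    fdr_threshold: float = 0.01,
    fdr_column: str = "fdr_either",
    require_consistent_sign: bool = True,
) -> pd.DataFrame:
    """Elements reproducibly called across every replicate experiment.

    An element is called when it meets ``fdr_threshold`` in all replicates
    and (optionally) its effect sizes share a sign.  Returns one row per
    called element with the direction and per-replicate summary.
    """
    _require_columns(
        element_results,
        ["element_id", "experiment_id", "effect_z", fdr_column],
        "combine_replicates",
    )
    n_exp = element_results["experiment_id"].nunique()
    if n_exp < 2:
        raise ValueError("replicate combination needs at least 2 experiments")
    rows = []
    for element_id, sub in element_results.groupby("element_id", sort=True):
        if sub["experiment_id"].nunique() < n_exp:
            continue
        fdr = sub[fdr_column].to_numpy(dtype=float)
        eff = sub["effect_z"].to_numpy(dtype=float)
        if np.any(fdr >= fdr_threshold):
            continue
        signs = np.sign(eff)
        if require_consistent_sign and len(set(signs[signs != 0])) > 1:
            continue
        rows.append(
            {
                "element_id": element_id,
                "n_replicates": int(len(sub)),
                "direction": "up" if eff.mean() > 0 else "down",
                "mean_effect_z": float(eff.mean()),
                "max_fdr": float(fdr.max()),
            }
        )
    if not rows:
        warnings.warn(
            "no element passed the reproducibility filter in every replicate",
            stacklevel=2,
        )
        return pd.DataFrame(
            columns=["element_id", "n_replicates", "direction", "mean_effect_z", "max_fdr"]
        )
    return pd.DataFrame(rows)
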