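"""Synthetic sorting-screen generator with known ground truth.

The generative model mirrors a pooled FACS screen: guide abundances after
library construction are Poisson, the number of cells carrying each guide is
Poisson around that abundance, each cell's (quantile-normalized) expression is
Normal with the guide's assigned shift, cells are gated into bins by their
standard-normal bounds, and sequencing reads per guide per bin are negative
binomial around the guide's share of the bin at a fixed read depth per cell.

Two perturbation modes are supported: "mean_altering" shifts every cell of a
guide by mu_g SDs, "proportion_altering" moves a fraction r_g of cells to a
mode shifted by 1 SD (so the average effect is r_g x 1 SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bins import SortingBin, quantile_bins_to_z

__all__ = [
    "SimConfig",
    "SimulatedScreen",
    "default_extreme_bins",
    "simulate_library",
    "simulate_sorted_cells",
    "simulate_reads",
    "simulate_screen",
]

MEAN_ALTERING = "mean_altering"
PROPORTION_ALTERING = "proportion_altering"


def default_extreme_bins() -> list[SortingBin]:
    """Six 10% bins on the distribution extremes (three per tail)."""
    return quantile_bins_to_z(
        [
            ("A", 0.0, 0.1),
            ("B", 0.1, 0.2),
            ("C", 0.2, 0.3),
            ("D", 0.7, 0.8),
            ("E", 0.8, 0.9),
            ("F", 0.9, 1.0),
        ]
    )


@dataclass
class SimConfig:
    """Study conditions for one simulated screen.

    Defaults reproduce the benchmark design: 200 targeted elements with 5
    guides each, of which the first 100 are effective with effects 0.01..1.00
    (mean shifts in SD units, or responder fractions), plus 1000 negative
    controls; guide abundance Poisson(1000); ten sequencing reads per sorted
    cell; six 10% extreme bins.
    """

    n_elements: int = 200
    guides_per_element: int = 5
    n_controls: int = 1000
    library_mean: float = 1000.0
    read_depth_factor: float = 10.0
    bins: list[SortingBin] = field(default_factory=default_extreme_bins)
    mode: str = MEAN_ALTERING
    effect_grid: np.ndarray | None = None
    responder_shift: float = 1.0
    seed: int = 0

    def resolved_effect_grid(self) -> np.ndarray:
        """Assigned effects of the effective elements.

        Default: half the elements (at most 100) are effective, with effects
        evenly spaced up to 1.0 — for 200 elements this is the benchmark grid
        0.01, 0.02, ..., 1.00.
        """
        if self.effect_grid is not None:
            grid = np.asarray(self.effect_grid, dtype=float)
        else:
            k = min(100, max(1, self.n_elements // 2))
            grid = np.arange(1, k + 1) / k
        if grid.size > self.n_elements:
            raise ValueError("more effects than elements")
        if np.any(grid <= 0):
            raise ValueError("assigned effects must be positive")
        return grid

    def __post_init__(self) -> None:
        if self.mode not in (MEAN_ALTERING, PROPORTION_ALTERING):
            raise ValueError(f"unknown simulation mode {self.mode!r}")
        if self.library_mean < 0 or self.read_depth_factor <= 0:
            raise ValueError("rates must be positive")


@dataclass
class SimulatedScreen:
    """Simulator output: count table, bin definitions, and ground truth."""

    counts: pd.DataFrame
    bins: list[SortingBin]
    truth: pd.DataFrame
    config: SimConfig


def simulate_library(
    n_guides: int, library_mean: float, rng: np.random.Generator
) -> np.ndarray:
    """Guide abundances after library construction: A_g ~ Poisson(mean)."""
    return rng.poisson(library_mean, size=n_guides)


def simulate_sorted_cells(
    abundances: np.ndarray,
    effects: np.ndarray,
    bins: Sequence[SortingBin],
    rng: np.random.Generator,
    *,
    mode: str = MEAN_ALTERING,
    responder_shift: float = 1.0,
) -> np.ndarray:
    """Sort cells into bins, one row per guide, one column per bin.

    The cell count per guide is ``S_g ~ Poisson(A_g)``.  Each cell's
    expression is Normal(effect, 1) in mean-altering mode; in
    proportion-altering mode a cell responds with probability ``effect`` and
    is then shifted by ``responder_shift`` SDs.  A cell lands in bin b when
    ``Z_b0 <= E < Z_b1``; cells outside every gate are discarded (unsorted
    middle of the distribution).
    """
    abundances = np.asarray(abundances)
    effects = np.asarray(effects, dtype=float)
    if abundances.shape != effects.shape:
        raise ValueError("abundances and effects must align per guide")
    n_guides = abundances.size
    cells = rng.poisson(abundances)
    guide_of_cell = np.repeat(np.arange(n_guides), cells)
    expr = rng.standard_normal(guide_of_cell.size)
    if mode == MEAN_ALTERING:
        expr += np.repeat(effects, cells)
    elif mode == PROPORTION_ALTERING:
        responds = rng.random(guide_of_cell.size) < np.repeat(effects, cells)
        expr += responder_shift * responds
    else:
        raise ValueError(f"unknown simulation mode {mode!r}")
    counts = np.empty((n_guides, len(bins)), dtype=np.int64)
    for j, b in enumerate(bins):
        inside = (expr >= b.start_z) & (expr < b.end_z)
        counts[:, j] = np.bincount(guide_of_cell[inside], minlength=n_guides)
    return counts


def simulate_reads(
    cell_counts: np.ndarray,
    rng: np.random.Generator,
    *,
    read_depth_factor: float = 10.0,
) -> np.ndarray:
    """Sequencing reads per guide per bin.

    Reads for guide g in bin b follow a negative binomial whose size is the
    bin's read budget (``read_depth_factor`` reads per sorted cell in the
    bin) and whose expected guide share equals the guide's share of cells in
    that bin, i.e. ``r_bg ~ NB(size = d * sum_i S_bi, prob = 1 - S_bg /
    sum_i S_bi)`` in the successes/failure-count convention.
    """
    cell_counts = np.asarray(cell_counts)
    n_guides, n_bins = cell_counts.shape
    reads = np.zeros_like(cell_counts, dtype=np.int64)
    for j in range(n_bins):
        total = int(cell_counts[:, j].sum())
        if total == 0:
            warnings.warn(f"bin column {j} sorted zero cells; zero reads", stacklevel=2)
            continue
        frac = cell_counts[:, j] / total
        np.clip(frac, 0.0, 1.0 - 1e-12, out=frac)
        size = int(round(read_depth_factor * total))
        reads[:, j] = rng.negative_binomial(size, 1.0 - frac)
    return reads


def _guide_table(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Guide annotations, element truth table, and per-guide effects."""
    grid = config.resolved_effect_grid()
    n_eff = grid.size
    element_ids = [f"e{i:04d}" for i in range(config.n_elements)]
    element_effects = np.concatenate(
        [grid, np.zeros(config.n_elements - n_eff)]
    )
    if config.mode == MEAN_ALTERING:
        avg = element_effects
        truth_col = "true_mu"
    else:
        avg = element_effects * config.responder_shift
        truth_col = "true_r"
    truth = pd.DataFrame(
        {
            "element_id": element_ids,
            "is_effective": np.arange(config.n_elements) < n_eff,
            truth_col: element_effects,
            "average_effect": avg,
        }
    )
    rows = []
    for i, el in enumerate(element_ids):
        for j in range(config.guides_per_element):
            rows.append((f"{el}_g{j}", False, el))
    for c in range(config.n_controls):
        rows.append((f"nc{c:04d}", True, np.nan))
    guides = pd.DataFrame(rows, columns=["guide_id", "is_negative_control", "element_label"])
    per_guide = np.concatenate(
        [
            np.repeat(element_effects, config.guides_per_element),
            np.zeros(config.n_controls),
        ]
    )
    return guides, truth, per_guide


def simulate_screen(config: SimConfig) -> SimulatedScreen:
    """Run the full generator and return analysis-ready tables.

    The count table has the columns the guide-level analysis expects
    (``guide_id``, ``is_negative_control``, ``element_label``, one column per
    bin, ``unsorted``); the truth table records each element's assigned
    effect and whether it is effective.  A single seeded generator drives
    library construction, cell sorting, and read sampling in that order, so
    identical configs give identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    guides, truth, effects = _guide_table(config)
    n_guides = len(guides)
    abundances = simulate_library(n_guides, config.library_mean, rng)
    cell_counts = simulate_sorted_cells(
        abundances,
        effects,
        config.bins,
        rng,
        mode=config.mode,
        responder_shift=config.responder_shift,
    )
    reads = simulate_reads(
        cell_counts, rng, read_depth_factor=config.read_depth_factor
    )
    # Unsorted input library: same read model applied to guide abundances.
    lib_total = int(abundances.sum())
    lib_frac = abundances / max(lib_total, 1)
    np.clip(lib_frac, 0.0, 1.0 - 1e-12, out=lib_frac)
    unsorted = rng.negative_binomial(
        int(round(config.read_depth_factor * lib_total)), 1.0 - lib_frac
    )
    counts = guides.copy()
    for j, b in enumerate(config.bins):
        counts[b.bin_id] = reads[:, j]
    counts["unsorted"] = unsorted
    return SimulatedScreen(counts=counts, bins=list(config.bins), truth=truth, config=config)
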