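"""Sorting-bin geometry in quantile and standard-normal space.

A FACS sorting gate is characterized by the cumulative fraction of all sorted
cells that falls below its lower and upper expression bounds.  Because the
analysis model quantile-normalizes the expression axis to a standard normal
reference, every bin is equivalently described by the pair of standard-normal
Z bounds capturing the same quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "BinValidationError",
    "SortingBin",
    "quantile_bins_to_z",
    "validate_bins",
    "bin_occupancy",
    "occupancy",
]


class BinValidationError(ValueError):
    """Raised when a bin definition violates the gate geometry contract."""


@dataclass(frozen=True)
class SortingBin:
    """One FACS gate: a contiguous quantile slice of the expression axis.

    Attributes
    ----------
    bin_id : str
        Short label (e.g. ``"A"``, ``"F"``, ``"low10"``).
    start_q, end_q : float
        Cumulative fraction of sorted cells at the lower/upper bound, in [0, 1].
    start_z, end_z : float
        Standard-normal bounds capturing the same quantiles; may be ``-inf`` /
        ``+inf`` for gates touching the distribution extremes.
    """

    bin_id: str
    start_q: float
    end_q: float
    start_z: float
    end_z: float

    @property
    def fraction(self) -> float:
        """Share of all cells sorted into this bin (``end_q - start_q``)."""
        return self.end_q - self.start_q


def quantile_bins_to_z(
    bin_fractions: Iterable[tuple[str, float, float]],
) -> list[SortingBin]:
    """Convert cumulative-quantile gate bounds to standard-normal bounds.

    Parameters
    ----------
    bin_fractions
        Ordered ``(bin_id, start_q, end_q)`` triples.  Quantiles must lie in
        [0, 1], each bin must satisfy ``start_q < end_q``, and bins may not
        overlap in quantile space (touching bounds are allowed).

    Returns
    -------
    list of SortingBin with ``start_z = Phi^-1(start_q)`` and
    ``end_z = Phi^-1(end_q)`` (``Phi^-1(0) = -inf``, ``Phi^-1(1) = +inf``).
    """
    bins: list[SortingBin] = []
    for bin_id, start_q, end_q in bin_fractions:
        if not (0.0 <= start_q < end_q <= 1.0):
            raise BinValidationError(
                f"bin {bin_id!r}: quantile bounds ({start_q}, {end_q}) must "
                f"satisfy 0 <= start_q < end_q <= 1"
            )
        bins.append(
            SortingBin(
                bin_id=str(bin_id),
                start_q=float(start_q),
                end_q=float(end_q),
                start_z=float(norm.ppf(start_q)),
                end_z=float(norm.ppf(end_q)),
            )
        )
    validate_bins(bins)
    return bins


def validate_bins(bins: Sequence[SortingBin], *, q_tol: float = 1e-9) -> None:
    """Check the gate-set invariants for one experiment.

    Bins must not overlap in quantile space, total coverage must not exceed 1,
    and each bin's Z bounds must capture the same probability mass as its
    quantile bounds (``Phi(end_z) - Phi(start_z) == fraction`` within q_tol).
    """
    if not bins:
        raise BinValidationError("experiment defines no sorting bins")
    ids = [b.bin_id for b in bins]
    if len(set(ids)) != len(ids):
        raise BinValidationError(f"duplicate bin ids: {sorted(ids)}")
    ordered = sorted(bins, key=lambda b: b.start_q)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start_q < prev.end_q - q_tol:
            raise BinValidationError(
                f"bins {prev.bin_id!r} and {cur.bin_id!r} overlap in quantile "
                f"space ({prev.end_q} > {cur.start_q})"
            )
    total = sum(b.fraction for b in bins)
    if total > 1.0 + 1e-9:
        raise BinValidationError(f"bin fractions sum to {total:.6f} > 1")
    for b in bins:
        if not b.start_z < b.end_z:
            raise BinValidationError(
                f"bin {b.bin_id!r}: start_z {b.start_z} must be < end_z {b.end_z}"
            )
        mass = norm.cdf(b.end_z) - norm.cdf(b.start_z)
        if abs(mass - b.fraction) > max(q_tol, 1e-9):
            raise BinValidationError(
                f"bin {b.bin_id!r}: Z bounds capture mass {mass:.12f} but "
                f"quantile bounds imply {b.fraction:.12f}"
            )


def occupancy(start_z, end_z, mu):
    """Fraction of a Normal(mu, 1) population falling between two Z bounds.

    Vectorized over any broadcastable combination of bounds and shifts.
    """
    mu = np.asarray(mu, dtype=float)
    return norm.cdf(np.asarray(end_z) - mu) - norm.cdf(np.asarray(start_z) - mu)


def bin_occupancy(bin: SortingBin, mu: float):
    """Expected fraction of cells with mean shift ``mu`` sorted into ``bin``.

    This is ``S(b, mu) = Phi(Z_b1 - mu) - Phi(Z_b0 - mu)``; at ``mu = 0`` it
    equals the bin's share of all sorted cells.
    """
    return occupancy(bin.start_z, bin.end_z, mu)
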