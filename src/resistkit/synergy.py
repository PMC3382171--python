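"""Bliss-independence synergy analysis of drug-combination dose matrices.

Under Bliss independence two drugs act like independent probabilistic events,
so the expected combined inhibition is E = A + B - A*B, with A and B the
single-agent inhibition fractions.  The excess of the observed combination
inhibition over this expectation, floored at zero, is the dBLISS score:
0 means additivity and values approaching 1 mean strong synergy (e.g. two
individually inactive drugs that together kill everything).  Single-agent
inhibitions are read off the measured zero-dose edges of the same dose
matrix, never from fitted curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CombinationSurface",
    "SynergyWindow",
    "bliss_expected",
    "delta_bliss_surface",
    "max_synergy_window",
    "InvalidDataError",
    "IncompleteMatrixError",
]


class InvalidDataError(ValueError):
    pass


class IncompleteMatrixError(ValueError):
    """The observed matrix lacks a zero-dose row or column."""


def bliss_expected(inh_a, inh_b):
    """Bliss-independence expected inhibition A + B - A*B.

    Inputs are clipped into [0, 1]; the result is symmetric, bounded in
    [0, 1] and monotone non-decreasing in each argument.
    """
    a = np.asarray(inh_a, dtype=float)
    b = np.asarray(inh_b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidDataError("single-agent inhibitions must be finite")
    a = np.clip(a, 0.0, 1.0)
    b = np.clip(b, 0.0, 1.0)
    out = a + b - a * b
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CombinationSurface:
    """A combination dose grid with observed, Bliss-expected and dBLISS matrices.

    ``doses_a`` index the rows and ``doses_b`` the columns, each in ascending
    order with a leading zero dose; row/column 0 of ``observed`` are thus the
    single-agent curves.  ``delta`` is floored at zero; ``signed_excess``
    retains negative values (antagonism).
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    delta: np.ndarray
    signed_excess: np.ndarray


@dataclass(frozen=True)
class SynergyWindow:
    """Lowest dose corner above which dBLISS stays within a fraction of its max."""

    min_dose_a: float | None
    min_dose_b: float | None
    threshold_fraction: float
    max_delta: float
    empty: bool = False


def delta_bliss_surface(observed, doses_a, doses_b) -> CombinationSurface:
    """Compute Bliss-expected and dBLISS matrices from an observed TGI grid.

    ``observed[i, j]`` is the TGI at (doses_a[i], doses_b[j]); both dose axes
    must include a zero-dose edge carrying the single-agent responses.
    Observed values are clipped into [0, 1] before the Bliss arithmetic.
    """
    obs = np.asarray(observed, dtype=float)
    da = np.asarray(doses_a, dtype=float)
    db = np.asarray(doses_b, dtype=float)
    if obs.shape != (da.size, db.size):
        raise InvalidDataError(
            f"observed shape {obs.shape} does not match dose axes ({da.size}, {db.size})"
        )
    if not np.all(np.isfinite(obs)):
        raise InvalidDataError("observed TGI matrix contains non-finite values")
    ia = np.flatnonzero(da == 0)
    ib = np.flatnonzero(db == 0)
    if ia.size != 1 or ib.size != 1:
        raise IncompleteMatrixError(
            "observed matrix must include exactly one zero-dose row and column "
            "(the single-agent edges)"
        )
    ia, ib = int(ia[0]), int(ib[0])
    if np.any(np.diff(da) <= 0) or np.any(np.diff(db) <= 0):
        raise InvalidDataError("dose axes must be strictly increasing (zero edge first)")
    clipped = np.clip(obs, 0.0, 1.0)
    single_a = clipped[:, ib]  # drug A alone, along rows
    single_b = clipped[ia, :]  # drug B alone, along columns
    expected = bliss_expected(single_a[:, None], single_b[None, :])
    signed = clipped - expected
    delta = np.maximum(signed, 0.0)
    return CombinationSurface(
        doses_a=da, doses_b=db, observed=obs, expected=expected,
        delta=delta, signed_excess=signed,
    )


def max_synergy_window(
    surface: CombinationSurface, threshold_fraction: float = 0.9
) -> SynergyWindow:
    """Find the lowest dose corner whose entire >=dose block is near-maximally synergistic.

    Scans every grid corner (a, b) with both doses nonzero and keeps those
    for which all cells with dose_a >= a and dose_b >= b satisfy
    delta >= threshold_fraction * max(delta); among valid corners the one
    with the smallest dose product (ties: smallest dose_a) is returned.
    Returns an empty window when max(delta) == 0.
    """
    if not (0 < threshold_fraction <= 1):
        raise InvalidDataError("threshold_fraction must lie in (0, 1]")
    delta = surface.delta
    if delta.size == 0:
        raise InvalidDataError("delta matrix is empty")
    max_delta = float(delta.max())
    if max_delta <= 0:
        return SynergyWindow(None, None, threshold_fraction, max_delta, empty=True)
    cut = threshold_fraction * max_delta
    ok = delta >= cut
    best = None
    for i in np.flatnonzero(surface.doses_a > 0):
        for j in np.flatnonzero(surface.doses_b > 0):
            if ok[i:, j:].all():
                key = (surface.doses_a[i] * surface.doses_b[j], surface.doses_a[i])
                if best is None or key < best[0]:
                    best = (key, float(surface.doses_a[i]), float(surface.doses_b[j]))
    if best is None:
        return SynergyWindow(None, None, threshold_fraction, max_delta, empty=True)
    return SynergyWindow(best[1], best[2], threshold_fraction, max_delta)
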