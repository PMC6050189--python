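"""Hill numbers and Shannon entropy for a single aggregate.

The Hill number of order ``q`` converts any of the classical diversity
indices into an *effective number of elements*: the number of equally
frequent species or alleles an idealised aggregate would need in order to
score the same index value as the observed one.  For a relative-abundance
vector ``p = (p_1, ..., p_S)``,

    qD = ( sum_i p_i ** q ) ** (1 / (1 - q)),        q >= 0, q != 1,

with the continuous limit at ``q = 1`` given by ``exp(H)`` where
``H = -sum_i p_i ln p_i`` is Shannon entropy (natural log throughout).
``q = 0`` is richness (a plain count of elements present), ``q = 2`` is the
inverse Simpson concentration (the effective number implied by expected
heterozygosity when applied to allele frequencies).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "validate_abundances",
    "shannon_entropy",
    "hill_number",
    "diversity_profile",
]

#: |q - 1| below this is treated as exactly q = 1 (closed form, no interpolation).
_Q_ONE_TOL = 1e-10
#: vectors whose sum deviates from 1 by more than this are rejected, smaller
#: deviations are silently renormalised (tolerates file rounding).
_SUM_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def validate_abundances(p: Iterable[float]) -> np.ndarray:
    """Validate and renormalise a relative-abundance vector.

    Parameters
    ----------
    p
        Sequence of S relative frequencies. Entries must be non-negative,
        at least one must be positive, and the sum must be within 1e-6 of 1
        (raw counts should be divided by their total first).

    Returns
    -------
    numpy.ndarray
        The vector renormalised to sum exactly to 1.
    """
    arr = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("abundance vector must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        idx = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValidationError(f"non-finite frequency at index {idx}")
    neg = np.flatnonzero(arr < 0)
    if neg.size:
        raise ValidationError(f"negative frequency at index {int(neg[0])}")
    total = float(arr.sum())
    if total <= 0.0:
        raise ValidationError("abundance vector sums to zero")
    if abs(total - 1.0) > _SUM_TOL:
        raise ValidationError(
            f"abundance vector sums to {total:.8g}, not 1 (tolerance {_SUM_TOL:g}); "
            "normalise counts before calling"
        )
    return arr / total


def shannon_entropy(p: Iterable[float]) -> float:
    """Shannon entropy ``H = -sum p_i ln p_i`` in nats.

    Zero frequencies contribute nothing (the ``0 ln 0 = 0`` convention), so
    padded tables with absent elements are handled transparently.
    """
    arr = validate_abundances(p)
    pos = arr[arr > 0]
    return float(-(pos * np.log(pos)).sum())


def hill_number(p: Iterable[float], q: float) -> float:
    """Effective number of elements of order ``q`` for frequencies ``p``.

    ``q = 0`` counts the elements present; ``q = 1`` is ``exp(H)``; other
    orders use the power-mean form. The result always lies in ``[1, S]``.
    """
    if q < 0:
        raise ValidationError(f"diversity order q must be >= 0, got {q}")
    arr = validate_abundances(p)
    pos = arr[arr > 0]
    if q == 0:
        return float(pos.size)
    if abs(q - 1.0) < _Q_ONE_TOL:
        return float(np.exp(-(pos * np.log(pos)).sum()))
    return float(np.power((pos**q).sum(), 1.0 / (1.0 - q)))


def diversity_profile(
    p: Iterable[float], q_grid: Sequence[float]
) -> list[tuple[float, float]]:
    """Evaluate the Hill-number profile ``q -> qD`` on a grid of orders.

    The profile is non-increasing in ``q``: low orders emphasise rare
    elements (richness at ``q = 0``), high orders emphasise dominant ones.
    Pairs are returned in the input order of ``q_grid``.
    """
    grid = list(q_grid)
    if not grid:
        raise ValidationError("q_grid must not be empty")
    arr = validate_abundances(p)
    return [(float(q), hill_number(arr, float(q))) for q in grid]
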