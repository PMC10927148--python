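"""Confidence-to-rank transforms.

The heart of the fuzzy-rank fusion scheme is a fixed, strictly decreasing
map from a classifier's confidence score ``x`` in ``[0, 1]`` to a continuous
("fuzzy") rank value in ``[0, 1]``, where 0 is the best attainable rank.
The shipped transform is a re-parameterized Mitscherlich function — the
exponential saturation law familiar from crop-yield response curves —
rewritten as a decreasing map

    R(x) = 2 * (1 - 2**(x - 1))  ==  2 - 2**x

so that R(0) = 1 (the value reused as the rank penalty for classes outside
the top-k) and R(1) = 0. Its slope steepens as ``x`` approaches 1, so the
transform is most sensitive exactly where confident predictions need to be
told apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "RankFunction",
    "MITSCHERLICH",
    "mitscherlich_rank",
    "rank_transform",
    "get_rank_function",
    "register_rank_function",
]

#: slack allowed outside [0, 1] before an input is treated as a hard error;
#: softmax outputs saved at limited precision routinely overshoot by ulps.
DOMAIN_TOLERANCE = 1e-9


def _check_domain(x: np.ndarray, context: str = "") -> np.ndarray:
    """Clamp values within DOMAIN_TOLERANCE of [0,1]; raise beyond it."""
    bad = (x < -DOMAIN_TOLERANCE) | (x > 1.0 + DOMAIN_TOLERANCE)
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        value = x[tuple(idx)]
        where = f" at {context}{tuple(int(i) for i in idx)}" if x.ndim else ""
        raise ValueError(
            f"confidence score {value!r} outside [0, 1]{where}; "
            f"values may deviate by at most {DOMAIN_TOLERANCE}"
        )
    return np.clip(x, 0.0, 1.0)


def mitscherlich_rank(cof):
    """Map a confidence score to its Mitscherlich fuzzy rank.

    Parameters
    ----------
    cof : float or array-like
        Confidence score(s) in ``[0, 1]``. Values outside the interval by
        more than 1e-9 raise ``ValueError``; smaller excursions are clamped.

    Returns
    -------
    float or ndarray
        ``2 * (1 - 2**(cof - 1))``, a rank value in ``[0, 1]``; strictly
        decreasing in ``cof`` with ``f(0) = 1`` and ``f(1) = 0``.

    Examples
    --------
    >>> mitscherlich_rank(0.0)
    1.0
    >>> mitscherlich_rank(1.0)
    0.0
    """
    arr = np.asarray(cof, dtype=float)
    arr = _check_domain(arr)
    out = 2.0 * (1.0 - np.exp2(arr - 1.0))
    # endpoints are exact in IEEE arithmetic (2**-1 and 2**0 are exact),
    # but clip guards the interior against sub-ulp negatives
    out = np.clip(out, 0.0, 1.0)
    if np.isscalar(cof) or np.ndim(cof) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class RankFunction:
    """A named confidence-to-rank transform.

    Attributes
    ----------
    name : str
        Registry identifier.
    transform : callable
        Vectorized map from confidence in [0,1] to rank value in [0,1].
    penalty_rank : float
        The transform's value at confidence 0, used downstream as the rank
        penalty for classes outside a classifier's top-k. Must be exactly
        ``transform(0)``.
    """

    name: str
    transform: Callable = field(repr=False)
    penalty_rank: float = 1.0

    def __call__(self, cof):
        return self.transform(cof)


MITSCHERLICH = RankFunction(
    name="mitscherlich", transform=mitscherlich_rank, penalty_rank=1.0
)

_REGISTRY: dict[str, RankFunction] = {MITSCHERLICH.name: MITSCHERLICH}


def register_rank_function(fn: RankFunction) -> None:
    """Register an alternative transform (extension point; only the
    Mitscherlich transform ships)."""
    if not (abs(fn.transform(0.0) - fn.penalty_rank) < 1e-12):
        raise ValueError("penalty_rank must equal transform(0)")
    _REGISTRY[fn.name] = fn


def get_rank_function(name: str) -> RankFunction:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown rank function {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def rank_transform(scores, fn: RankFunction = MITSCHERLICH) -> np.ndarray:
    """Apply a rank transform elementwise to a confidence matrix.

    Parameters
    ----------
    scores : array-like, shape (n_samples, n_classes)
        Confidence matrix of one classifier; entries in [0, 1].
    fn : RankFunction
        The transform to apply (default: Mitscherlich).

    Returns
    -------
    ndarray of the same shape: the fuzzy-rank matrix.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        return arr.reshape(arr.shape)
    _check_domain(arr, context="(sample, class) ")
    return np.asarray(fn.transform(arr), dtype=float)
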