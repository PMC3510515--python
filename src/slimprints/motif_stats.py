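"""Motif-level significance from per-residue tail probabilities.

A candidate motif is a proximal grouping of defined residues, each carrying
an (approximately uniform under the null) tail probability p_RLC.  The raw
group score is the product

    p_motif = prod_x p_RLC_x

over the n defined positions.  p_motif is not comparable across motif sizes
— more factors means a smaller product — so it is converted into the
probability that a product of n independent Uniform(0,1) variables is at
most p_motif:

    Sig_motif = P(U_1 * ... * U_n <= p) = p * sum_{k=0}^{n-1} (-ln p)^k / k!

which is exactly the regularised upper incomplete gamma function Q(n, -ln p)
(since -ln of the product is Gamma(n, 1) distributed).  Sig_motif is uniform
under the null whatever n, making it a size-comparable significance score.

The incomplete-gamma form is the authoritative implementation (the series
loses precision for large n and tiny p); the explicit series is kept as an
independent cross-check.

Candidates whose defined positions have very unequal p_RLC values typically
reflect one anchored residue dragging weak neighbours along rather than a
coherently constrained motif; the anchor-variance filter discards them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaincc

ANCHOR_VARIANCE_DEFAULT = 0.05


@dataclass(frozen=True)
class MotifCandidate:
    """A scored grouping of defined query positions.

    ``defined_positions`` are 0-based internal indices, sorted ascending;
    rendering to 1-based happens at output time.
    """

    protein_id: str
    defined_positions: tuple[int, ...]
    pattern: str
    p_rlc_values: tuple[float, ...]
    p_motif: float
    sig_motif: float

    @property
    def n(self) -> int:
        return len(self.defined_positions)

    @property
    def start(self) -> int:
        """1-based position of the first defined residue."""
        return self.defined_positions[0] + 1

    @property
    def end(self) -> int:
        """1-based position of the last defined residue."""
        return self.defined_positions[-1] + 1

    @property
    def n_wildcards(self) -> int:
        return (self.defined_positions[-1] - self.defined_positions[0] + 1) - self.n


def _validate_probs(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one probability is required")
    if ((arr <= 0) | (arr > 1)).any():
        raise ValueError("probabilities must lie in (0, 1]")
    return arr


def p_motif(p_rlc_values) -> float:
    """Product of the per-residue tail probabilities over defined positions."""
    return float(np.prod(_validate_probs(p_rlc_values)))


def sig_motif(p: float, n: int) -> float:
    """CDF of a product of n independent Uniform(0,1) variables at p.

    Computed as the regularised upper incomplete gamma Q(n, -ln p).  Exact
    at both endpoints: sig_motif(1, n) = 1 and sig_motif(p -> 0, n) -> 0;
    for n = 1 it is the identity.
    """
    if not (0 < p <= 1):
        raise ValueError(f"p_motif must lie in (0, 1], got {p}")
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if p == 1.0:
        return 1.0
    if n == 1:
        return float(p)  # one uniform: identity, exact
    return float(gammaincc(n, -math.log(p)))


def sig_motif_series(p: float, n: int) -> float:
    """Closed-form series p * sum_{k<n} (-ln p)^k / k!  (cross-check form)."""
    if not (0 < p <= 1):
        raise ValueError(f"p_motif must lie in (0, 1], got {p}")
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n!r}")
    log_term = -math.log(p)
    total = 0.0
    term = 1.0
    for k in range(n):
        if k > 0:
            term *= log_term / k
        total += term
    return p * total


def anchor_variance_ok(
    p_rlc_values, threshold: float = ANCHOR_VARIANCE_DEFAULT, population: bool = True
) -> bool:
    """Accept a candidate unless its p_RLC values are too dispersed.

    Returns False (discard) iff the variance of the values exceeds
    ``threshold``.  Population variance by default; a single value always
    passes.
    """
    arr = _validate_probs(p_rlc_values)
    if arr.size == 1:
        return True
    ddof = 0 if population else 1
    return float(np.var(arr, ddof=ddof)) <= threshold
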