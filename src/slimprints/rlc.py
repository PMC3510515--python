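"""Relative local conservation (RLC) and its Gaussian tail probability.

A residue's raw conservation C_i says little on its own: disordered regions
drift, globular regions do not, so the interesting signal is conservation
*relative to the local background*.  The RLC score standardises C_i against
a window of flanking residues:

    RLC_i = (C_i - mean_i) / sigma_i

where the mean and standard deviation are taken over the residues within N
positions either side of i (i itself excluded; windows truncate at the
termini), weighted by similarity of disorder propensity.

The disorder weighting is asymmetric.  A window residue j at least as
disordered as i contributes fully (w_ij = 1); a residue more ordered than i
— likely under structural rather than motif constraint — is down-weighted
exponentially, w_ij = exp(-a * (d_i - d_j)), with a controlling strictness.
Under uniform disorder all weights are 1 and the score reduces to a plain
windowed z-score.

Treating RLC as standard normal gives each residue a heuristic upper-tail
probability p_RLC = P(Z >= RLC); on drifting (unconstrained) background
these are approximately uniform, which is what lets them be combined into
motif-level significance downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

#: mask reason codes used by RLCProfile and downstream masking
REASON_HOMOGENEOUS = "homogeneous"
REASON_SHORT_WINDOW = "short-window"


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder propensity d_x in [0, 1] (IUPred-style, higher = more disordered)."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1:
            raise ValueError("disorder scores must be one-dimensional")
        if ((s < 0) | (s > 1)).any():
            raise ValueError("disorder scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class RLCParams:
    """Window and weighting parameters.

    window_halfwidth: residues considered on each side of the focal residue.
    weight_strictness: exponent a of the asymmetric disorder weighting.
    sigma_floor: windows with weighted sigma below this are masked
        "homogeneous" (relative conservation is meaningless there).
    min_window: positions with fewer usable window residues than this
        (short sequences / extreme termini) are masked "short-window".
    weighted_sigma: use the disorder weights in sigma as well as the mean.
    """

    window_halfwidth: int = 30
    weight_strictness: float = 5.0
    sigma_floor: float = 0.01
    min_window: int = 10
    weighted_sigma: bool = True

    def __post_init__(self) -> None:
        if self.window_halfwidth < 1:
            raise ValueError("window_halfwidth must be >= 1")
        if self.weight_strictness <= 0:
            raise ValueError("weight_strictness must be positive")
        if self.sigma_floor <= 0:
            raise ValueError("sigma_floor must be positive")


@dataclass(frozen=True)
class RLCProfile:
    """Per-residue RLC score, tail probability, and window statistics.

    Masked positions carry NaN in ``rlc``/``p_rlc`` and a reason code in
    ``mask_reason`` ('' where defined).
    """

    rlc: np.ndarray
    p_rlc: np.ndarray
    window_mean: np.ndarray
    window_sigma: np.ndarray
    mask_reason: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.rlc)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.rlc)


def disorder_weights(
    i: int, window: np.ndarray, disorder: DisorderProfile, a: float
) -> np.ndarray:
    """Asymmetric disorder weights w_ij of window residues for focal residue i.

    w_ij = 1 where d_j >= d_i, exp(-a * (d_i - d_j)) where d_j < d_i.
    All weights lie in (0, 1]; under uniform disorder every weight is 1.
    """
    d = np.asarray(disorder.scores, dtype=float)
    window = np.asarray(window, dtype=int)
    if np.any(window == i):
        raise ValueError("window must exclude the focal residue")
    deficit = np.clip(d[i] - d[window], 0.0, None)
    return np.exp(-a * deficit)


def relative_local_conservation(
    conservation, disorder: DisorderProfile, params: RLCParams = RLCParams()
) -> RLCProfile:
    """Convert a conservation profile into RLC scores and tail probabilities.

    ``conservation`` is a ConservationProfile or 1-D array of C values; it
    must have the same length as ``disorder``.  Windows are truncated at the
    termini, never padded.
    """
    c = np.asarray(getattr(conservation, "scores", conservation), dtype=float)
    d = np.asarray(disorder.scores, dtype=float)
    if len(c) != len(d):
        raise ValueError("conservation and disorder profiles differ in length")
    n = len(c)
    half = params.window_halfwidth
    a = params.weight_strictness

    rlc = np.full(n, np.nan)
    p = np.full(n, np.nan)
    mean = np.full(n, np.nan)
    sigma = np.full(n, np.nan)
    reasons = [""] * n

    uniform = bool(np.all(d == d[0]))
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        window = np.concatenate([np.arange(lo, i), np.arange(i + 1, hi)])
        if len(window) < params.min_window:
            reasons[i] = REASON_SHORT_WINDOW
            continue
        if uniform:
            w = None
            cw = c[window]
            m = cw.mean()
            var = ((cw - m) ** 2).mean()
        else:
            w = disorder_weights(i, window, disorder, a)
            wsum = w.sum()
            cw = c[window]
            if wsum <= 1e-300:
                # every window residue infinitely down-weighted (extreme a):
                # no usable background
                reasons[i] = REASON_HOMOGENEOUS
                continue
            m = float(np.dot(w, cw) / wsum)
            if params.weighted_sigma:
                var = float(np.dot(w, (cw - m) ** 2) / wsum)
            else:
                um = cw.mean()
                var = float(((cw - um) ** 2).mean())
        s = np.sqrt(var)
        mean[i] = m
        sigma[i] = s
        if s < params.sigma_floor:
            reasons[i] = REASON_HOMOGENEOUS
            continue
        rlc[i] = (c[i] - m) / s
        p[i] = p_rlc(rlc[i])

    return RLCProfile(
        rlc=rlc,
        p_rlc=p,
        window_mean=mean,
        window_sigma=sigma,
        mask_reason=tuple(reasons),
    )


def p_rlc(rlc_value: float):
    """Upper-tail standard-normal probability P(Z >= rlc).

    Accepts a scalar or array; raises on non-finite input.
    """
    arr = np.asarray(rlc_value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("RLC value must be finite")
    out = norm.sf(arr)
    return float(out) if np.isscalar(rlc_value) or arr.ndim == 0 else out


def read_disorder_tsv(path, expected_length: int | None = None) -> DisorderProfile:
    """Read a disorder profile TSV: position (1-based), residue, score.

    A header line is tolerated.  Positions must be contiguous from 1.
    """
    scores: list[float] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            try:
                pos = int(row[0])
            except ValueError:
                continue  # header
            if pos != len(scores) + 1:
                raise ValueError(
                    f"disorder positions must be contiguous from 1; got {pos} "
                    f"at line {len(scores) + 1}"
                )
            scores.append(float(row[-1]))
    if expected_length is not None and len(scores) != expected_length:
        raise ValueError(
            f"disorder profile length {len(scores)} != query length {expected_length}"
        )
    return DisorderProfile(scores=np.asarray(scores))


def write_disorder_tsv(disorder: DisorderProfile, query_sequence: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tresidue\tdisorder\n")
        for i, (ch, s) in enumerate(zip(query_sequence, disorder.scores), start=1):
            fh.write(f"{i}\t{ch}\t{s:.6f}\n")
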