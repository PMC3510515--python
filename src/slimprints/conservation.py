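"""Per-column conservation of the orthologue alignment, in query coordinates.

The column score C_i is an identity-based, sequence-weighted information
content: the Shannon entropy of the weighted amino-acid frequencies in the
column (over the 20-letter alphabet, gap mass excluded and renormalised)
scaled to [0, 1] and multiplied by the non-gap weight fraction.  Identity
only — conservative substitutions are deliberately not rewarded, which
preserves the contrast between invariant motif residues and a drifting
disordered background.

Rows more distant from the query carry more weight: agreement between
divergent sequences is stronger evidence of constraint than agreement
between near-identical ones.  The query row itself is excluded from the
frequency counts, since it would contribute a constant self-match at every
column.

The exact scorer is a swappable strategy (``scorer`` argument of
:func:`column_conservation`); any callable with the same signature mapping a
column to [0, 1] can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .msa_io import GAP, STANDARD_AA, OrthologueAlignment, QueryColumnMap, query_distance

_LN20 = math.log(20.0)

#: Additive floor on raw distance weights so identical rows keep equal,
#: non-zero weight.
WEIGHT_FLOOR = 0.01


@dataclass(frozen=True)
class SequenceWeights:
    """Normalised non-negative weight per orthologue row (query excluded)."""

    row_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.row_ids):
            raise ValueError("one weight per orthologue row required")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class ConservationProfile:
    """Column conservation C_i in [0, 1], one value per query residue."""

    scores: np.ndarray
    alignment_id: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if ((s < -1e-12) | (s > 1 + 1e-12)).any():
            raise ValueError("conservation scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


def sequence_weights(aln: OrthologueAlignment) -> SequenceWeights:
    """Distance-based sequence weights for the orthologue rows.

    Raw weight of a row is its normalised distance to the query plus a small
    floor, then normalised to sum to one.  Identical rows therefore receive
    equal weight, and a set of equidistant rows is weighted uniformly.
    """
    if aln.n_orthologues < 1:
        raise ValueError("at least one orthologue row is required")
    ids, raw = [], []
    for k, (rid, _) in enumerate(aln.rows):
        if k == aln.query_row_index:
            continue
        ids.append(rid)
        raw.append(query_distance(aln, k) + WEIGHT_FLOOR)
    w = np.asarray(raw, dtype=float)
    return SequenceWeights(row_ids=tuple(ids), weights=w / w.sum())


def entropy_identity_score(
    residues: list[str], weights: np.ndarray
) -> float:
    """C for one column: (1 - H/H_max) * (1 - f_gap).

    ``residues`` holds one character per orthologue row.  Gap and ambiguity
    mass f_gap is removed from the frequencies, which are renormalised over
    the 20 standard amino acids before the entropy H is taken; the gap mass
    then penalises the score multiplicatively.  A column with no standard
    residue among the orthologues scores 0.
    """
    f: dict[str, float] = {}
    f_gap = 0.0
    for ch, w in zip(residues, weights):
        if ch == GAP or ch not in STANDARD_AA:
            f_gap += w
        else:
            f[ch] = f.get(ch, 0.0) + w
    non_gap = 1.0 - f_gap
    if non_gap <= 1e-12:
        return 0.0
    h = 0.0
    for mass in f.values():
        p = mass / non_gap
        h -= p * math.log(p)
    return (1.0 - h / _LN20) * non_gap


def column_conservation(
    aln: OrthologueAlignment,
    weights: SequenceWeights,
    qmap: QueryColumnMap,
    scorer=entropy_identity_score,
) -> ConservationProfile:
    """Score every query-residue column of the alignment.

    Only orthologue rows enter the frequencies; the returned profile has one
    score per query residue, in query order.
    """
    if len(qmap) == 0:
        raise ValueError("empty query-column map")
    orth_seqs = [seq for _, seq in aln.orthologue_rows]
    if len(orth_seqs) != len(weights.weights):
        raise ValueError("weights do not match alignment orthologue rows")
    w = np.asarray(weights.weights, dtype=float)
    scores = np.empty(len(qmap))
    for i, col in enumerate(qmap.residue_to_column):
        scores[i] = scorer([seq[col] for seq in orth_seqs], w)
    return ConservationProfile(scores=scores, alignment_id=aln.query_id)


def write_conservation_tsv(
    profile: ConservationProfile, query_sequence: str, path
) -> None:
    """Export C as TSV: residue_index (1-based), residue, score (6 dp)."""
    with open(path, "w") as fh:
        fh.write("position\tresidue\tconservation\n")
        for i, (ch, c) in enumerate(zip(query_sequence, profile.scores), start=1):
            fh.write(f"{i}\t{ch}\t{c:.6f}\n")
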