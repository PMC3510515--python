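"""Motif discovery: seed, extend, filter, score, and select conserved islands.

The search space of motifs is bounded by the known shape of short linear
motifs: at most ``l`` defined (non-wildcard) positions with at most ``g``
wildcards between consecutive defined positions.  Discovery proceeds
breadth-first:

1. every unmasked residue with RLC >= c becomes a single-position seed;
2. each candidate is repeatedly extended on either side by a search-space
   residue within the gap limit, merging duplicates reached by different
   extension orders, up to l defined positions;
3. candidates with over-dispersed p_RLC values (anchored-residue artefacts)
   or with long indels in matching orthologues are discarded;
4. survivors are scored (p_motif, Sig_motif) and those at or below the
   significance cutoff compete for a non-overlapping final set, greedily by
   ascending Sig_motif (ties: fewer wildcards, then leftmost).

The result is deterministic: identical input yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import msa_io
from .conservation import column_conservation, sequence_weights
from .msa_io import GAP, OrthologueAlignment, QueryColumnMap, query_column_map
from .motif_stats import (
    ANCHOR_VARIANCE_DEFAULT,
    MotifCandidate,
    anchor_variance_ok,
    p_motif,
    sig_motif,
)
from .rlc import DisorderProfile, RLCParams, RLCProfile, relative_local_conservation
from .search_space import (
    FeatureMask,
    SearchSpace,
    SearchSpaceParams,
    build_search_space,
)

CONTEXT_FLANK = 5


@dataclass(frozen=True)
class BuilderParams:
    """Motif-space and filtering parameters.

    rlc_cutoff: minimum RLC for a residue to enter the search space (c).
    max_defined: maximum number of defined positions (l).
    max_gap: maximum wildcards between consecutive defined positions (g).
    indel_tolerance: matching orthologues with an insertion or deletion of
        this many or more columns inside the motif span are disqualifying (d).
    sig_cutoff: maximum Sig_motif of a reported hit.
    anchor_variance: maximum variance of a candidate's p_RLC values.
    """

    rlc_cutoff: float = 0.0
    max_defined: int = 5
    max_gap: int = 2
    indel_tolerance: int = 2
    sig_cutoff: float = 0.05
    anchor_variance: float = ANCHOR_VARIANCE_DEFAULT

    def __post_init__(self) -> None:
        if self.max_defined < 1:
            raise ValueError("max_defined must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.indel_tolerance < 1:
            raise ValueError("indel_tolerance must be >= 1")


@dataclass(frozen=True)
class AlignmentFilterParams:
    """Row-level alignment preprocessing applied before discovery."""

    max_branch_distance: float = 0.9
    min_coverage: float = 0.8
    min_orthologues: int = 10


@dataclass(frozen=True)
class MotifHit(MotifCandidate):
    """A reported motif with rendering context and rank."""

    regex: str = ""
    context: str = ""
    rank: int = 0


def prepare_alignment(
    aln: OrthologueAlignment, filters: AlignmentFilterParams = AlignmentFilterParams()
) -> OrthologueAlignment:
    """Prune long branches, filter coverage, and require enough orthologues."""
    aln = msa_io.prune_long_branches(aln, filters.max_branch_distance)
    aln = msa_io.filter_coverage(aln, filters.min_coverage)
    return msa_io.require_min_orthologues(aln, filters.min_orthologues)


def seed_positions(
    space: SearchSpace, rlc_profile: RLCProfile, c: float
) -> list[int]:
    """Residues of the search space S: unmasked with RLC >= c (0-based)."""
    unmasked = space.unmasked
    rlc = rlc_profile.rlc
    return [
        i
        for i in range(len(space))
        if unmasked[i] and np.isfinite(rlc[i]) and rlc[i] >= c
    ]


def enumerate_candidates(
    seeds: list[int],
    stretch_id: np.ndarray,
    max_gap: int,
    max_defined: int,
) -> list[tuple[int, ...]]:
    """All position sets reachable by the seed/extend scheme, duplicates merged.

    Each candidate is a sorted tuple of 0-based positions, all within one
    unmasked stretch, consecutive positions at most ``max_gap`` wildcards
    apart, between 1 and ``max_defined`` positions.  The result is sorted
    for determinism.
    """
    seed_set = set(seeds)
    all_candidates: set[tuple[int, ...]] = {(p,) for p in seeds}
    frontier = list(all_candidates)
    reach = max_gap + 1
    for _ in range(1, max_defined):
        new: set[tuple[int, ...]] = set()
        for cand in frontier:
            lo, hi = cand[0], cand[-1]
            sid = stretch_id[lo]
            for r in range(lo - reach, lo):
                if r >= 0 and r in seed_set and stretch_id[r] == sid:
                    new.add((r,) + cand)
            for r in range(hi + 1, hi + reach + 1):
                if r in seed_set and stretch_id[r] == sid:
                    new.add(cand + (r,))
        new -= all_candidates
        all_candidates |= new
        frontier = list(new)
        if not frontier:
            break
    return sorted(all_candidates)


def indel_ok(
    aln: OrthologueAlignment,
    qmap: QueryColumnMap,
    positions: tuple[int, ...],
    d: int = 2,
) -> bool:
    """Check matching orthologues for disqualifying indels inside the motif span.

    An orthologue row *matches* the motif when it carries the query residue
    at every defined column.  For matching rows only, the maximal run of
    columns strictly between the first and last defined columns where either
    the row or the query is gapped is measured; a run of length >= d fails
    the candidate.  Non-matching rows are unconstrained.
    """
    cols = [qmap.column_of(p) for p in positions]
    c0, c1 = cols[0], cols[-1]
    if c1 - c0 < 2:
        return True
    qrow = aln.query_row
    for _, seq in aln.orthologue_rows:
        if any(seq[c] != qrow[c] for c in cols):
            continue  # not matching the motif: no constraint
        run = best = 0
        for c in range(c0 + 1, c1):
            if seq[c] == GAP or qrow[c] == GAP:
                run += 1
                best = max(best, run)
            else:
                run = 0
        if best >= d:
            return False
    return True


def pattern_string(
    positions: tuple[int, ...], query_sequence: str, wildcard: str = "x"
) -> str:
    """Render defined positions as residues and inter-position gaps as wildcards.

    With ``wildcard='.'`` this yields the regular-expression rendering.
    """
    out = []
    for k, pos in enumerate(positions):
        if k > 0:
            out.append(wildcard * (pos - positions[k - 1] - 1))
        out.append(query_sequence[pos])
    return "".join(out)


def context_string(
    positions: tuple[int, ...], query_sequence: str, flank: int = CONTEXT_FLANK
) -> str:
    """Motif span plus ``flank`` residues either side; defined residues uppercase."""
    lo = max(0, positions[0] - flank)
    hi = min(len(query_sequence), positions[-1] + flank + 1)
    defined = set(positions)
    return "".join(
        query_sequence[i].upper() if i in defined else query_sequence[i].lower()
        for i in range(lo, hi)
    )


@dataclass(frozen=True)
class DiscoveryResult:
    """Hits plus the intermediate profiles, for inspection and benchmarking."""

    hits: tuple[MotifHit, ...]
    candidates: tuple[MotifCandidate, ...]
    conservation: np.ndarray
    rlc_profile: RLCProfile
    space: SearchSpace
    alignment: OrthologueAlignment


def score_candidates(
    aln: OrthologueAlignment,
    qmap: QueryColumnMap,
    rlc_profile: RLCProfile,
    position_sets: list[tuple[int, ...]],
    params: BuilderParams,
) -> list[MotifCandidate]:
    """Apply anchor-variance and indel filters, then score the survivors."""
    seq = aln.query_sequence
    any_gap = _gap_presence(aln)
    out = []
    for positions in position_sets:
        p_values = tuple(float(rlc_profile.p_rlc[p]) for p in positions)
        if not anchor_variance_ok(p_values, params.anchor_variance):
            continue
        if len(positions) > 1 and any_gap is not None:
            c0 = qmap.column_of(positions[0])
            c1 = qmap.column_of(positions[-1])
            # only candidates whose column span contains a gap need the scan
            if any_gap[c0 + 1 : c1].any() and not indel_ok(
                aln, qmap, positions, params.indel_tolerance
            ):
                continue
        pm = p_motif(p_values)
        out.append(
            MotifCandidate(
                protein_id=aln.query_id,
                defined_positions=positions,
                pattern=pattern_string(positions, seq),
                p_rlc_values=p_values,
                p_motif=pm,
                sig_motif=sig_motif(pm, len(positions)),
            )
        )
    return out


def _gap_presence(aln: OrthologueAlignment) -> np.ndarray | None:
    """Per-column flag: does any row carry a gap?  None if the MSA is gap-free."""
    any_gap = np.zeros(aln.column_count, dtype=bool)
    for _, seq in aln.rows:
        if GAP in seq:
            any_gap |= np.frombuffer(seq.encode(), dtype=np.uint8) == ord(GAP)
    return any_gap if any_gap.any() else None


def select_nonoverlapping(
    candidates: list[MotifCandidate], sig_cutoff: float
) -> list[MotifCandidate]:
    """Greedy best-first selection of non-overlapping significant candidates.

    Ascending Sig_motif; ties broken by fewer wildcards, then leftmost
    start, then the position tuple itself (full determinism).  A candidate
    is accepted iff none of its defined positions appears in an already
    accepted one.
    """
    eligible = [c for c in candidates if c.sig_motif <= sig_cutoff]
    eligible.sort(
        key=lambda c: (c.sig_motif, c.n_wildcards, c.defined_positions[0], c.defined_positions)
    )
    taken: set[int] = set()
    out = []
    for cand in eligible:
        if taken.isdisjoint(cand.defined_positions):
            out.append(cand)
            taken.update(cand.defined_positions)
    return out


def discover(
    aln: OrthologueAlignment,
    disorder: DisorderProfile,
    masks: FeatureMask | None = None,
    rlc_params: RLCParams = RLCParams(),
    space_params: SearchSpaceParams = SearchSpaceParams(),
    builder_params: BuilderParams = BuilderParams(),
    filters: AlignmentFilterParams | None = None,
) -> DiscoveryResult:
    """Run the full discovery pipeline on one alignment.

    ``filters`` applies row-level alignment preprocessing first (pass None
    for an alignment that is already pruned and filtered); an alignment with
    too few orthologues raises InsufficientOrthologuesError.
    """
    if filters is not None:
        aln = prepare_alignment(aln, filters)
    if len(disorder) != aln.query_length:
        raise ValueError("disorder profile length does not match query")
    qmap = query_column_map(aln)
    weights = sequence_weights(aln)
    cons = column_conservation(aln, weights, qmap)
    rlc_profile = relative_local_conservation(cons, disorder, rlc_params)
    space = build_search_space(aln, qmap, rlc_profile, disorder, masks, space_params)

    seeds = seed_positions(space, rlc_profile, builder_params.rlc_cutoff)
    position_sets = enumerate_candidates(
        seeds, space.stretch_id, builder_params.max_gap, builder_params.max_defined
    )
    candidates = score_candidates(aln, qmap, rlc_profile, position_sets, builder_params)
    selected = select_nonoverlapping(candidates, builder_params.sig_cutoff)

    seq = aln.query_sequence
    hits = tuple(
        MotifHit(
            protein_id=c.protein_id,
            defined_positions=c.defined_positions,
            pattern=c.pattern,
            p_rlc_values=c.p_rlc_values,
            p_motif=c.p_motif,
            sig_motif=c.sig_motif,
            regex=pattern_string(c.defined_positions, seq, wildcard="."),
            context=context_string(c.defined_positions, seq),
            rank=rank,
        )
        for rank, c in enumerate(selected, start=1)
    )
    return DiscoveryResult(
        hits=hits,
        candidates=tuple(candidates),
        conservation=cons.scores,
        rlc_profile=rlc_profile,
        space=space,
        alignment=aln,
    )


HIT_COLUMNS = (
    "protein_id",
    "start",
    "end",
    "pattern",
    "regex",
    "n_defined",
    "defined_positions",
    "p_rlc_values",
    "p_motif",
    "sig_motif",
    "context",
)


def write_hits_tsv(hits, path_or_handle) -> None:
    """Write hits as TSV, one row per hit, 1-based coordinates.

    Accepts a filesystem path or an open text handle.
    """
    if hasattr(path_or_handle, "write"):
        _write_hits(hits, path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _write_hits(hits, fh)


def _write_hits(hits, fh) -> None:
    fh.write("\t".join(HIT_COLUMNS) + "\n")
    for h in hits:
        fh.write(
            "\t".join(
                (
                    h.protein_id,
                    str(h.start),
                    str(h.end),
                    h.pattern,
                    h.regex,
                    str(h.n),
                    ",".join(str(p + 1) for p in h.defined_positions),
                    ",".join(f"{p:.6g}" for p in h.p_rlc_values),
                    f"{h.p_motif:.6g}",
                    f"{h.sig_motif:.6g}",
                    h.context,
                )
            )
            + "\n"
        )
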