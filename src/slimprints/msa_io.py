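"""Orthologue alignment input, row-level filtering and query-coordinate indexing.

The motif statistics downstream are computed on a multiple alignment of a
query protein against its orthologues.  Divergent rows and poorly covered
rows add alignment noise rather than signal, so before any conservation is
computed the alignment is pruned (long-branch removal), coverage-filtered,
and required to keep a minimum number of orthologues.  All filters are
row-wise predicates against the fixed query row, so they are idempotent and
commute.

Internally every coordinate is 0-based; user-facing output is 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import AlignIO

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"


class AlignmentError(ValueError):
    """Raised when an alignment violates a structural invariant."""


class InsufficientOrthologuesError(ValueError):
    """Raised when too few orthologue rows survive filtering.

    Carries the observed orthologue count in :attr:`count`.
    """

    def __init__(self, count: int, required: int):
        self.count = count
        self.required = required
        super().__init__(
            f"insufficient orthologues: {count} retained, {required} required"
        )


@dataclass(frozen=True)
class OrthologueAlignment:
    """An aligned query protein plus orthologue rows.

    rows are (sequence_id, aligned string) pairs over uppercase amino-acid
    codes and the gap symbol '-'; ambiguity codes such as 'X' are permitted
    and are treated as matching nothing.
    """

    query_id: str
    rows: tuple[tuple[str, str], ...]
    query_row_index: int

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise AlignmentError("ragged alignment: rows differ in length")
        if not (0 <= self.query_row_index < len(self.rows)):
            raise AlignmentError("query row index out of range")
        qid, qseq = self.rows[self.query_row_index]
        if qid != self.query_id:
            raise AlignmentError("query_row_index does not point at query_id")
        if all(c == GAP for c in qseq):
            raise AlignmentError("query row contains no residues")
        for rid, seq in self.rows:
            for c in seq:
                if c != GAP and not ("A" <= c <= "Z"):
                    raise AlignmentError(
                        f"illegal character {c!r} in row {rid!r}"
                    )

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1])

    @property
    def query_row(self) -> str:
        return self.rows[self.query_row_index][1]

    @property
    def query_sequence(self) -> str:
        """Ungapped query sequence."""
        return self.query_row.replace(GAP, "")

    @property
    def query_length(self) -> int:
        return len(self.query_sequence)

    @property
    def orthologue_rows(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            r for k, r in enumerate(self.rows) if k != self.query_row_index
        )

    @property
    def n_orthologues(self) -> int:
        return len(self.rows) - 1


@dataclass(frozen=True)
class QueryColumnMap:
    """Bijection from query residue index to alignment column (both 0-based)."""

    residue_to_column: tuple[int, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.residue_to_column)

    def column_of(self, residue_index: int) -> int:
        return self.residue_to_column[residue_index]

    def residue_of(self, column: int) -> int:
        """Inverse lookup; raises KeyError for columns where the query is gapped."""
        try:
            return self.residue_to_column.index(column)
        except ValueError:
            raise KeyError(f"query is gapped at column {column}") from None


def read_alignment(path, format: str, query_id: str) -> OrthologueAlignment:
    """Read an aligned FASTA or Clustal file and locate the query row.

    Residue case is normalised to upper; row order is preserved.
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(path, format)
    except ValueError as exc:
        raise AlignmentError(f"could not parse {path}: {exc}") from exc
    rows = tuple((rec.id, str(rec.seq).upper()) for rec in msa)
    query_index = next((k for k, (rid, _) in enumerate(rows) if rid == query_id), None)
    if query_index is None:
        raise AlignmentError(f"query not found: no row with id {query_id!r}")
    return OrthologueAlignment(query_id=query_id, rows=rows, query_row_index=query_index)


def query_distance(aln: OrthologueAlignment, row_index: int) -> float:
    """Normalised distance of a row to the query.

    1 minus the fraction of identically matching columns among columns where
    both the row and the query are non-gap.  Ambiguity characters never match.
    A row sharing no non-gap column with the query is maximally distant (1.0).
    """
    qseq = aln.query_row
    seq = aln.rows[row_index][1]
    shared = matched = 0
    for a, b in zip(qseq, seq):
        if a != GAP and b != GAP:
            shared += 1
            if a == b and a in STANDARD_AA:
                matched += 1
    if shared == 0:
        return 1.0
    return 1.0 - matched / shared


def prune_long_branches(
    aln: OrthologueAlignment, max_distance: float = 0.9
) -> OrthologueAlignment:
    """Drop orthologue rows whose distance to the query exceeds ``max_distance``.

    The query row is never pruned.  Retained rows are unchanged and keep
    their order; an alignment reduced to the query alone is still valid.
    """
    keep = [
        row
        for k, row in enumerate(aln.rows)
        if k == aln.query_row_index or query_distance(aln, k) <= max_distance
    ]
    return _rebuild(aln, keep)


def filter_coverage(
    aln: OrthologueAlignment, min_coverage: float = 0.8
) -> OrthologueAlignment:
    """Keep orthologues aligned to strictly more than ``min_coverage`` of the query.

    Coverage counts query residues over which the orthologue has a non-gap
    character, regardless of identity; ambiguity codes count as covered.
    The inequality is strict, so exactly 80% of the query is insufficient at
    the 0.8 default.
    """
    qcols = [c for c, ch in enumerate(aln.query_row) if ch != GAP]
    threshold = min_coverage * len(qcols)
    keep = []
    for k, (rid, seq) in enumerate(aln.rows):
        if k == aln.query_row_index:
            keep.append((rid, seq))
            continue
        covered = sum(1 for c in qcols if seq[c] != GAP)
        if covered > threshold:
            keep.append((rid, seq))
    return _rebuild(aln, keep)


def require_min_orthologues(
    aln: OrthologueAlignment, min_orthologues: int = 10
) -> OrthologueAlignment:
    """Pass the alignment through iff it retains enough orthologue rows.

    Raises :class:`InsufficientOrthologuesError` (carrying the observed
    count) when fewer than ``min_orthologues`` non-query rows remain.
    """
    if aln.n_orthologues < min_orthologues:
        raise InsufficientOrthologuesError(aln.n_orthologues, min_orthologues)
    return aln


def query_column_map(aln: OrthologueAlignment) -> QueryColumnMap:
    """Map each query residue to the alignment column holding it."""
    cols = tuple(c for c, ch in enumerate(aln.query_row) if ch != GAP)
    return QueryColumnMap(residue_to_column=cols)


def _rebuild(
    aln: OrthologueAlignment, rows: list[tuple[str, str]]
) -> OrthologueAlignment:
    query_index = next(
        k for k, (rid, _) in enumerate(rows) if rid == aln.query_id
    )
    return OrthologueAlignment(
        query_id=aln.query_id, rows=tuple(rows), query_row_index=query_index
    )


def write_alignment_fasta(aln: OrthologueAlignment, path) -> None:
    """Write the alignment as aligned FASTA (gap '-')."""
    with open(path, "w") as fh:
        for rid, seq in aln.rows:
            fh.write(f">{rid}\n{seq}\n")
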