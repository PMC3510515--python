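"""Masking of motif-deficient regions: the residue search space S.

Short linear motifs live in intrinsically disordered regions, so everything
that is not credible motif territory is masked before discovery: annotated
features (domains, transmembrane and extracellular segments), ordered
residues (low disorder score), weakly aligned "gappy" columns, windows of
homogeneous conservation where a relative score is meaningless, and — after
all residue-level rules — any surviving unmasked stretch too short to hold
a motif.

Masking happens *after* RLC computation: masked residues are excluded from
the search space but still contribute to the window statistics of their
neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_io import GAP, OrthologueAlignment, QueryColumnMap
from .rlc import DisorderProfile, RLCProfile

MASK_LABELS = ("domain", "transmembrane", "extracellular", "custom")

REASON_FEATURE = "feature"
REASON_ORDERED = "ordered"
REASON_GAPPY = "gappy"
REASON_SHORT_STRETCH = "short-stretch"
UNMASKED = "unmasked"

#: residue-level reasons in precedence order (first applicable wins)
_RESIDUE_REASONS = (REASON_FEATURE, REASON_ORDERED, REASON_GAPPY)


@dataclass(frozen=True)
class FeatureMask:
    """Feature intervals on the query, 1-based inclusive coordinates."""

    intervals: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self) -> None:
        for start, end, label in self.intervals:
            if not (1 <= start <= end):
                raise ValueError(f"invalid interval ({start}, {end})")
            if label not in MASK_LABELS:
                raise ValueError(f"unknown mask label {label!r}")

    def covers(self, length: int) -> np.ndarray:
        """Boolean array (0-based) of residues inside any interval."""
        out = np.zeros(length, dtype=bool)
        for start, end, _ in self.intervals:
            if end > length:
                raise ValueError(
                    f"interval ({start}, {end}) exceeds query length {length}"
                )
            out[start - 1 : end] = True
        return out


@dataclass(frozen=True)
class SearchSpaceParams:
    iupred_cutoff: float = 0.3
    gap_fraction: float = 0.25
    min_stretch: int = 10


@dataclass(frozen=True)
class SearchSpace:
    """Per-residue mask status plus the maximal unmasked stretches.

    ``status`` holds 'unmasked' or a reason code per residue (0-based);
    ``stretches`` are maximal unmasked runs as 0-based half-open intervals,
    each of length >= min_stretch.  ``stretch_id`` maps a residue to its
    stretch index, -1 if masked.
    """

    status: tuple[str, ...]
    stretches: tuple[tuple[int, int], ...]
    stretch_id: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.status)

    @property
    def unmasked(self) -> np.ndarray:
        return np.array([s == UNMASKED for s in self.status])

    def stretches_1based(self) -> list[tuple[int, int]]:
        return [(a + 1, b) for a, b in self.stretches]


def column_gap_fractions(
    aln: OrthologueAlignment, qmap: QueryColumnMap
) -> np.ndarray:
    """Fraction of orthologue rows gapped at each query-residue column.

    Counts rows, not sequence weights; ambiguity characters are not gaps
    here (they occupy the column).
    """
    orth = aln.orthologue_rows
    if not orth:
        raise ValueError("alignment has no orthologue rows")
    out = np.empty(len(qmap))
    for i, col in enumerate(qmap.residue_to_column):
        out[i] = sum(1 for _, seq in orth if seq[col] == GAP) / len(orth)
    return out


def build_search_space(
    aln: OrthologueAlignment,
    qmap: QueryColumnMap,
    rlc_profile: RLCProfile,
    disorder: DisorderProfile,
    masks: FeatureMask | None = None,
    params: SearchSpaceParams = SearchSpaceParams(),
) -> SearchSpace:
    """Apply every masking rule and derive the unmasked stretches.

    A residue is masked if any of the following holds: it lies inside a
    feature interval; its disorder score is strictly below iupred_cutoff;
    strictly more than ``gap_fraction`` of its column's orthologue rows are
    gaps; its RLC window was flagged homogeneous or short.  Finally any
    maximal unmasked run shorter than ``min_stretch`` is masked whole.
    """
    n = len(disorder)
    if len(rlc_profile) != n or len(qmap) != n:
        raise ValueError("profiles and alignment query length disagree")
    masks = masks or FeatureMask()

    feature = masks.covers(n)
    ordered = np.asarray(disorder.scores) < params.iupred_cutoff
    gappy = column_gap_fractions(aln, qmap) > params.gap_fraction

    status = []
    for i in range(n):
        if feature[i]:
            status.append(REASON_FEATURE)
        elif ordered[i]:
            status.append(REASON_ORDERED)
        elif gappy[i]:
            status.append(REASON_GAPPY)
        elif rlc_profile.mask_reason[i]:
            status.append(rlc_profile.mask_reason[i])
        else:
            status.append(UNMASKED)

    # enforce the minimum stretch length on the residue-level result
    stretches: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if status[i] != UNMASKED:
            i += 1
            continue
        j = i
        while j < n and status[j] == UNMASKED:
            j += 1
        if j - i < params.min_stretch:
            for k in range(i, j):
                status[k] = REASON_SHORT_STRETCH
        else:
            stretches.append((i, j))
        i = j

    stretch_id = np.full(n, -1, dtype=int)
    for sid, (a, b) in enumerate(stretches):
        stretch_id[a:b] = sid

    return SearchSpace(
        status=tuple(status),
        stretches=tuple(stretches),
        stretch_id=stretch_id,
    )


def read_mask_tsv(path) -> FeatureMask:
    """Read feature intervals from TSV (start, end, label), 1-based inclusive."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                start, end = int(parts[0]), int(parts[1])
            except ValueError:
                continue  # header
            label = parts[2] if len(parts) > 2 else "custom"
            if label not in MASK_LABELS:
                label = "custom"
            intervals.append((start, end, label))
    return FeatureMask(intervals=tuple(intervals))


def read_mask_gff3(path) -> FeatureMask:
    """Read feature intervals from a GFF3 file on the query sequence.

    The GFF3 ``type`` column is used as the label where it matches a known
    label, otherwise 'custom'; coordinates are already 1-based inclusive.
    """
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            ftype = cols[2].lower()
            label = ftype if ftype in MASK_LABELS else "custom"
            intervals.append((int(cols[3]), int(cols[4]), label))
    return FeatureMask(intervals=tuple(intervals))


def read_mask(path, format: str = "auto") -> FeatureMask:
    if format == "auto":
        format = "gff3" if str(path).endswith((".gff", ".gff3")) else "tsv"
    if format == "gff3":
        return read_mask_gff3(path)
    return read_mask_tsv(path)


def write_mask_tsv(masks: FeatureMask, path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tlabel\n")
        for start, end, label in masks.intervals:
            fh.write(f"{start}\t{end}\t{label}\n")
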