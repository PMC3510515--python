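import itertools

import numpy as np
import pytest

from slimprints.motif_builder import (
    BuilderParams,
    discover,
    enumerate_candidates,
    indel_ok,
    pattern_string,
    context_string,
    seed_positions,
    select_nonoverlapping,
    write_hits_tsv,
)
from slimprints.motif_stats import MotifCandidate
from slimprints.msa_io import query_column_map
from slimprints.rlc import RLCProfile
from slimprints.search_space import SearchSpace, UNMASKED
from slimprints.synthetic import SyntheticSpec, generate, planted_spec
from .conftest import make_alignment


def toy_space(n, masked=(), min_stretch=1):
    """A SearchSpace with the given residues masked ('custom' reason)."""
    status = [UNMASKED] * n
    for i in masked:
        status[i] = "feature"
    stretches = []
    stretch_id = np.full(n, -1, dtype=int)
    i = 0
    while i < n:
        if status[i] != UNMASKED:
            i += 1
            continue
        j = i
        while j < n and status[j] == UNMASKED:
            j += 1
        if j - i >= min_stretch:
            stretch_id[i:j] = len(stretches)
            stretches.append((i, j))
        else:
            for k in range(i, j):
                status[k] = "short-stretch"
        i = j
    return SearchSpace(status=tuple(status), stretches=tuple(stretches), stretch_id=stretch_id)


def toy_rlc(values):
    v = np.asarray(values, dtype=float)
    from scipy.stats import norm

    return RLCProfile(
        rlc=v,
        p_rlc=norm.sf(v),
        window_mean=np.zeros_like(v),
        window_sigma=np.ones_like(v),
        mask_reason=tuple("" if np.isfinite(x) else "short-window" for x in v),
    )


def brute_force_candidates(seeds, stretch_id, max_gap, max_defined):
    """Independent oracle: filter all position subsets by the motif-shape rules."""
    seeds = sorted(seeds)
    out = set()
    for size in range(1, max_defined + 1):
        for combo in itertools.combinations(seeds, size):
            ok = all(
                b - a <= max_gap + 1 for a, b in zip(combo, combo[1:])
            ) and len({stretch_id[p] for p in combo}) == 1
            if ok:
                out.add(tuple(combo))
    return out


class TestSeeds:
    def test_seeds_at_rlc_cutoff(self):
        space = toy_space(3)
        prof = toy_rlc([-1.0, 0.5, 2.0])
        assert seed_positions(space, prof, 0.0) == [1, 2]

    def test_all_masked_gives_no_seeds(self):
        space = toy_space(3, masked=(0, 1, 2))
        prof = toy_rlc([1.0, 1.0, 1.0])
        assert seed_positions(space, prof, 0.0) == []

    def test_infinite_cutoff_gives_no_seeds(self):
        space = toy_space(3)
        prof = toy_rlc([1.0, 2.0, 3.0])
        assert seed_positions(space, prof, float("inf")) == []


class TestExtension:
    def test_extension_within_gap(self):
        space = toy_space(20)
        cands = enumerate_candidates([10, 12], space.stretch_id, max_gap=2, max_defined=2)
        assert (10, 12) in cands

    def test_extension_beyond_gap_rejected(self):
        space = toy_space(20)
        cands = enumerate_candidates([10, 14], space.stretch_id, max_gap=2, max_defined=2)
        assert (10, 14) not in cands
        assert cands == [(10,), (14,)]

    def test_extension_on_either_side(self):
        space = toy_space(20)
        cands = enumerate_candidates([9, 10, 12], space.stretch_id, max_gap=2, max_defined=3)
        assert (9, 10, 12) in cands

    def test_candidates_never_cross_stretch_boundary(self):
        # positions 9 and 11 are 2 apart but in different stretches
        space = toy_space(21, masked=(10,))
        cands = enumerate_candidates([9, 11], space.stretch_id, max_gap=2, max_defined=2)
        assert (9, 11) not in cands

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        masked = tuple(np.flatnonzero(rng.random(n) < 0.25))
        space = toy_space(n, masked=masked, min_stretch=3)
        rlc_values = rng.standard_normal(n)
        prof = toy_rlc(rlc_values)
        seeds = seed_positions(space, prof, 0.0)
        got = set(enumerate_candidates(seeds, space.stretch_id, 2, 5))
        expected = brute_force_candidates(seeds, space.stretch_id, 2, 5)
        assert got == expected


class TestIndelFilter:
    def test_matching_row_without_gaps_tolerated(self):
        aln = make_alignment("AYRPPALR", "AYRPPALR")
        qmap = query_column_map(aln)
        assert indel_ok(aln, qmap, (0, 1, 4), d=2)

    def test_matching_row_with_long_gap_rejected(self):
        #           motif columns 0 and 4; 2-gap run strictly inside
        aln = make_alignment("AYRPP", "AY--P")
        qmap = query_column_map(aln)
        assert not indel_ok(aln, qmap, (0, 4), d=2)

    def test_single_gap_below_tolerance_kept(self):
        aln = make_alignment("AYRPP", "AYR-P")
        qmap = query_column_map(aln)
        assert indel_ok(aln, qmap, (0, 4), d=2)

    def test_non_matching_row_unconstrained(self):
        # row differs at a defined column, so its gaps are ignored
        aln = make_alignment("AYRPP", "WY--P")
        qmap = query_column_map(aln)
        assert indel_ok(aln, qmap, (0, 4), d=2)

    def test_query_insertion_counts_as_gap_run(self):
        # orthologue carries a 2-residue insertion: gap run in the query row
        aln = make_alignment("AY--PP", "AYWWPP")
        qmap = query_column_map(aln)  # query residues: A Y P P
        assert not indel_ok(aln, qmap, (0, 3), d=2)
        assert indel_ok(aln, qmap, (0, 3), d=3)


class TestRendering:
    def test_pattern_with_wildcards(self):
        assert pattern_string((1, 4), "AYRPPAL") == "YxxP"
        assert pattern_string((1, 4), "AYRPPAL", wildcard=".") == "Y..P"

    def test_adjacent_positions(self):
        assert pattern_string((2, 3), "AYRPPAL") == "RP"

    def test_single_position(self):
        assert pattern_string((1,), "AYRPPAL") == "Y"

    def test_context_highlights_defined_residues(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        ctx = context_string((7, 9), seq, flank=3)
        assert ctx == "fghIkLmnp"


def _candidate(positions, sig, protein_id="P"):
    return MotifCandidate(
        protein_id=protein_id,
        defined_positions=positions,
        pattern="",
        p_rlc_values=(0.01,) * len(positions),
        p_motif=0.01 ** len(positions),
        sig_motif=sig,
    )


class TestSelection:
    def test_overlapping_candidates_keep_best(self):
        a = _candidate((10, 12), 1e-6)
        b = _candidate((12, 14), 1e-4)
        assert select_nonoverlapping([b, a], 0.05) == [a]

    def test_non_overlapping_both_kept_in_rank_order(self):
        a = _candidate((10, 12), 1e-4)
        b = _candidate((20, 22), 1e-6)
        assert select_nonoverlapping([a, b], 0.05) == [b, a]

    def test_cutoff_applied(self):
        a = _candidate((10, 12), 0.2)
        assert select_nonoverlapping([a], 0.05) == []

    def test_tie_break_prefers_fewer_wildcards_then_leftmost(self):
        wide = _candidate((10, 13), 1e-5)
        tight = _candidate((20, 21), 1e-5)
        right = _candidate((30, 31), 1e-5)
        got = select_nonoverlapping([wide, right, tight], 0.05)
        assert got[0] is tight  # fewer wildcards first
        assert got[1] is right  # then leftmost among equals
        assert got[2] is wide


class TestDiscover:
    def test_planted_motif_is_top_hit(self):
        spec = planted_spec(120, random_seed=42)
        data = generate(spec)
        result = discover(data.alignment, data.disorder, data.masks)
        planted = set(spec.planted_motifs[0].positions)
        assert result.hits, "no hits returned"
        assert planted <= set(result.hits[0].defined_positions)
        assert result.hits[0].sig_motif < 1e-3

    def test_all_hits_satisfy_contracts(self):
        spec = planted_spec(80, random_seed=11)
        data = generate(spec)
        params = BuilderParams()
        result = discover(data.alignment, data.disorder, data.masks, builder_params=params)
        unmasked = result.space.unmasked
        taken = set()
        for hit in result.hits:
            assert hit.sig_motif <= params.sig_cutoff
            assert np.var(hit.p_rlc_values) <= params.anchor_variance
            for p in hit.defined_positions:
                assert unmasked[p]
                assert result.rlc_profile.rlc[p] >= params.rlc_cutoff
                assert p not in taken
                taken.add(p)
            assert hit.p_motif == pytest.approx(np.prod(hit.p_rlc_values), rel=1e-12)

    def test_null_hits_respect_cutoff(self):
        data = generate(SyntheticSpec(protein_length=200, random_seed=1))
        result = discover(data.alignment, data.disorder, data.masks)
        for hit in result.hits:
            assert hit.sig_motif <= 0.05

    def test_rejects_mismatched_disorder_length(self):
        data = generate(SyntheticSpec(protein_length=50, random_seed=0))
        short = generate(SyntheticSpec(protein_length=40, random_seed=0))
        with pytest.raises(ValueError):
            discover(data.alignment, short.disorder, None)

    def test_byte_identical_reruns(self, tmp_path):
        spec = planted_spec(60, random_seed=5, protein_length=200)
        out = []
        for k in range(2):
            data = generate(spec)
            result = discover(data.alignment, data.disorder, data.masks)
            path = tmp_path / f"hits{k}.tsv"
            write_hits_tsv(result.hits, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]
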