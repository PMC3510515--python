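import numpy as np
import pytest

from slimprints.conservation import column_conservation, sequence_weights
from slimprints.msa_io import query_column_map
from slimprints.rlc import DisorderProfile, relative_local_conservation
from slimprints.search_space import (
    FeatureMask,
    SearchSpaceParams,
    build_search_space,
    column_gap_fractions,
    read_mask,
    write_mask_tsv,
    REASON_FEATURE,
    REASON_GAPPY,
    REASON_ORDERED,
    REASON_SHORT_STRETCH,
    UNMASKED,
)
from slimprints.synthetic import SyntheticSpec, generate
from .conftest import make_alignment


def pipeline_inputs(seed=3, length=120, **kwargs):
    """A clean synthetic protein (no gaps) plus its profiles."""
    data = generate(SyntheticSpec(protein_length=length, random_seed=seed, **kwargs))
    aln = data.alignment
    qmap = query_column_map(aln)
    cons = column_conservation(aln, sequence_weights(aln), qmap)
    return aln, qmap, cons, data.disorder


class TestResidueRules:
    def test_clean_disordered_protein_fully_unmasked(self):
        aln, qmap, cons, disorder = pipeline_inputs()
        prof = relative_local_conservation(cons, disorder)
        space = build_search_space(aln, qmap, prof, disorder)
        assert space.unmasked.all()
        assert space.stretches == ((0, 120),)

    def test_disorder_below_cutoff_masked_strictly(self):
        aln, qmap, cons, _ = pipeline_inputs()
        d = np.full(120, 0.6)
        d[40] = 0.29  # below
        d[41] = 0.30  # exactly at the boundary: stays unmasked
        disorder = DisorderProfile(scores=d)
        prof = relative_local_conservation(cons, disorder)
        space = build_search_space(aln, qmap, prof, disorder)
        assert space.status[40] == REASON_ORDERED
        assert space.status[41] == UNMASKED

    def test_gap_fraction_masked_strictly_above_quarter(self):
        # 10 orthologues; 3 gaps (0.30) masked, 2 gaps (0.20) and exact 25% not
        query = "A" * 40
        orths = []
        for k in range(10):
            row = list("A" * 40)
            if k < 3:
                row[10] = "-"
            if k < 2:
                row[20] = "-"
            orths.append("".join(row))
        aln = make_alignment(query, *orths)
        qmap = query_column_map(aln)
        frac = column_gap_fractions(aln, qmap)
        assert frac[10] == pytest.approx(0.3)
        assert frac[20] == pytest.approx(0.2)
        disorder = DisorderProfile(scores=np.full(40, 0.6))
        cons = column_conservation(aln, sequence_weights(aln), qmap)
        prof = relative_local_conservation(cons, disorder)
        space = build_search_space(aln, qmap, prof, disorder)
        assert space.status[10] == REASON_GAPPY
        assert space.status[20] != REASON_GAPPY

    def test_exact_quarter_not_masked(self):
        query = "A" * 40
        orths = []
        for k in range(8):
            row = list("C" * 40)
            if k < 2:  # 2/8 = exactly 0.25
                row[5] = "-"
            orths.append("".join(row))
        aln = make_alignment(query, *orths)
        qmap = query_column_map(aln)
        assert column_gap_fractions(aln, qmap)[5] == pytest.approx(0.25)
        disorder = DisorderProfile(scores=np.full(40, 0.6))
        cons = column_conservation(aln, sequence_weights(aln), qmap)
        prof = relative_local_conservation(cons, disorder)
        space = build_search_space(aln, qmap, prof, disorder)
        assert space.status[5] != REASON_GAPPY

    def test_homogeneous_windows_propagate_from_rlc(self):
        aln, qmap, _, disorder = pipeline_inputs()
        flat = np.full(120, 0.5)  # sigma = 0 everywhere
        prof = relative_local_conservation(flat, disorder)
        space = build_search_space(aln, qmap, prof, disorder)
        assert not space.unmasked.any()
        assert set(space.status) == {"homogeneous"}

    def test_feature_interval_masked(self):
        aln, qmap, cons, disorder = pipeline_inputs()
        prof = relative_local_conservation(cons, disorder)
        masks = FeatureMask(intervals=((31, 60, "domain"),))
        space = build_search_space(aln, qmap, prof, disorder, masks)
        assert all(space.status[i] == REASON_FEATURE for i in range(30, 60))
        assert space.status[29] == UNMASKED
        assert space.status[60] == UNMASKED


class TestShortStretch:
    def test_nine_residue_island_masked_whole(self):
        aln, qmap, cons, _ = pipeline_inputs()
        d = np.full(120, 0.6)
        d[:50] = 0.1
        d[59:] = 0.1  # unmasked island = positions 50..58 (9 residues)
        disorder = DisorderProfile(scores=d)
        prof = relative_local_conservation(cons, disorder)
        space = build_search_space(aln, qmap, prof, disorder)
        assert all(space.status[i] == REASON_SHORT_STRETCH for i in range(50, 59))
        assert space.stretches == ()

    def test_ten_residue_island_survives(self):
        aln, qmap, cons, _ = pipeline_inputs()
        d = np.full(120, 0.6)
        d[:50] = 0.1
        d[60:] = 0.1  # island = positions 50..59 (10 residues)
        disorder = DisorderProfile(scores=d)
        prof = relative_local_conservation(cons, disorder)
        space = build_search_space(aln, qmap, prof, disorder)
        assert space.stretches == ((50, 60),)
        assert space.stretch_id[55] == 0
        assert space.stretch_id[49] == -1


class TestProperties:
    def test_adding_feature_never_unmasks(self):
        aln, qmap, cons, disorder = pipeline_inputs(seed=9)
        prof = relative_local_conservation(cons, disorder)
        base = build_search_space(aln, qmap, prof, disorder)
        more = build_search_space(
            aln, qmap, prof, disorder, FeatureMask(intervals=((20, 35, "custom"),))
        )
        assert not (more.unmasked & ~base.unmasked).any()

    def test_masking_is_a_fixed_point(self):
        aln, qmap, cons, _ = pipeline_inputs(seed=5)
        d = np.full(120, 0.6)
        d[30:45] = 0.1
        disorder = DisorderProfile(scores=d)
        prof = relative_local_conservation(cons, disorder)
        space = build_search_space(aln, qmap, prof, disorder)
        # re-express the masked set as feature intervals: result unchanged
        intervals = []
        for i, s in enumerate(space.status):
            if s != UNMASKED:
                intervals.append((i + 1, i + 1, "custom"))
        again = build_search_space(
            aln, qmap, prof, disorder, FeatureMask(intervals=tuple(intervals))
        )
        np.testing.assert_array_equal(space.unmasked, again.unmasked)
        assert space.stretches == again.stretches


class TestMaskIO:
    def test_tsv_roundtrip(self, tmp_path):
        masks = FeatureMask(intervals=((5, 10, "domain"), (20, 25, "transmembrane")))
        path = tmp_path / "mask.tsv"
        write_mask_tsv(masks, path)
        assert read_mask(path).intervals == masks.intervals

    def test_gff3(self, tmp_path):
        path = tmp_path / "mask.gff3"
        path.write_text(
            "##gff-version 3\n"
            "q\tsrc\tdomain\t5\t10\t.\t.\t.\tID=d1\n"
            "q\tsrc\tsignal_peptide\t1\t3\t.\t.\t.\tID=s1\n"
        )
        masks = read_mask(path)
        assert masks.intervals == ((5, 10, "domain"), (1, 3, "custom"))

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            FeatureMask(intervals=((10, 5, "domain"),))
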