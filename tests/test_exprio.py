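import numpy as np
import pandas as pd
import pytest

from exonsplice import exprio
from exonsplice.exprio import (AnnotationError, ExpressionIOError,
                               ExpressionSet, TranscriptModel)

from oracles import ptc_distance_enumerated, spliced_positions


def _model(strand="+", exons=((0, 100), (200, 300)), cds=((10, 100), (200, 250)),
           tid="t1"):
    return TranscriptModel(gene_id="g1", transcript_id=tid, chrom="chr1",
                           strand=strand, exons=exons, cds=cds)


class TestTranscriptModel:
    def test_single_exon_cds_equals_exon(self):
        m = TranscriptModel("g", "t", "c", "+", ((0, 99),), ((0, 99),))
        assert m.coding_length == 99
        assert m.spliced_length == 99
        assert m.frame_valid
        assert m.final_junction_spliced is None

    def test_minus_strand_transcription_order(self):
        m = _model(strand="-")
        assert m.exons == ((0, 100), (200, 300))          # genomic order kept
        assert m.exons_stranded == ((200, 300), (0, 100))  # 5'->3' reversed

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_spliced_coordinates_match_base_enumeration(self, strand):
        """Derived spliced coordinates agree with the base-by-base oracle."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(2, 6)
            pos, exons = 0, []
            for _ in range(n):
                pos += int(rng.integers(50, 300))
                L = int(rng.integers(30, 200))
                exons.append((pos, pos + L))
                pos += L
            # CDS from inside the first stranded exon into a later exon
            first = exons[0] if strand == "+" else exons[-1]
            last_idx = int(rng.integers(1, n))
            cds = []
            lo = min(last_idx, n - 1)
            chosen = exons[:lo + 1] if strand == "+" else exons[n - 1 - lo:]
            for k, (a, b) in enumerate(chosen):
                s = a + 5 if (strand == "+" and k == 0) else a
                e = b - 5 if (strand == "-" and k == len(chosen) - 1) else b
                if e > s:
                    cds.append((s, e))
            m = TranscriptModel("g", "t", "c", strand, tuple(exons), tuple(cds))
            bases = spliced_positions(m)
            assert len(bases) == m.spliced_length
            # spot-check offsets of arbitrary exonic bases
            for g in bases[:: max(1, len(bases) // 7)]:
                assert bases[m.spliced_offset(g)] == g
            if m.final_junction_spliced is not None:
                assert m.stop_spliced_end is not None
                dist = m.final_junction_spliced - m.stop_spliced_end
                assert dist == ptc_distance_enumerated(m)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(AnnotationError):
            TranscriptModel("g", "t", "c", "+", ((0, 100), (50, 150)))

    def test_cds_outside_exons_rejected(self):
        with pytest.raises(AnnotationError, match="t1"):
            _model(cds=((150, 180),))


class TestAnnotationIO:
    def test_round_trip(self, tmp_path, noise_free_sim):
        """load(write(models)) reproduces every transcript model exactly."""
        path = tmp_path / "ann.gtf"
        exprio.write_annotation(noise_free_sim.models, path)
        loaded = exprio.load_annotation(path)
        key = lambda m: m.transcript_id
        assert sorted(loaded, key=key) == sorted(noise_free_sim.models, key=key)

    def test_cds_outside_exons_names_transcript(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        attrs = 'gene_id "g1"; transcript_id "tx9";'
        gtf.write_text(
            "\n".join([
                f"chr1\tx\texon\t1\t100\t.\t+\t.\t{attrs}",
                f"chr1\tx\tCDS\t150\t200\t.\t+\t0\t{attrs}",
            ]) + "\n")
        with pytest.raises(AnnotationError, match="tx9"):
            exprio.load_annotation(gtf)


def _tiny_files(tmp_path, matrix_vals, with_const=True):
    samples = ["s1", "s2"]
    mat = pd.DataFrame(matrix_vals, index=["p1"], columns=samples)
    mat.to_csv(tmp_path / "m.tsv", sep="\t", index_label="probeset_id")
    pd.DataFrame({
        "probeset_id": ["p1"], "gene_id": ["g1"], "chrom": ["c"],
        "start": [0], "end": [10], "constitutive": [True], "tier": ["core"],
    }).to_csv(tmp_path / "map.tsv", sep="\t", index=False)
    return tmp_path / "m.tsv", tmp_path / "map.tsv"


class TestLoadExpression:
    def test_linear_heuristic_log2(self, tmp_path):
        m, mp = _tiny_files(tmp_path, [[1024.0, 2048.0]])
        es = exprio.load_expression(m, mp)
        assert es.intensities.loc["p1", "s1"] == pytest.approx(10.0)

    def test_log2_scale_left_alone(self, tmp_path):
        m, mp = _tiny_files(tmp_path, [[8.0, 9.0]])
        es = exprio.load_expression(m, mp)
        assert es.intensities.loc["p1", "s1"] == pytest.approx(8.0)

    def test_non_numeric_cell_located(self, tmp_path):
        _, mp = _tiny_files(tmp_path, [[8.0, 9.0]])
        (tmp_path / "m.tsv").write_text(
            "probeset_id\ts1\ts2\np1\t8.0\toops\n")
        with pytest.raises(ExpressionIOError, match="p1.*s2"):
            exprio.load_expression(tmp_path / "m.tsv", mp)

    def test_orphan_probeset_rejected(self, tmp_path):
        m, mp = _tiny_files(tmp_path, [[8.0, 9.0]])
        mat = pd.read_csv(m, sep="\t", index_col=0)
        mat.loc["p_orphan"] = [7.0, 7.0]
        mat.to_csv(m, sep="\t", index_label="probeset_id")
        with pytest.raises(ExpressionIOError, match="p_orphan"):
            exprio.load_expression(m, mp)

    def test_sample_mismatch_listed(self, tmp_path):
        m, mp = _tiny_files(tmp_path, [[8.0, 9.0]])
        pd.DataFrame({"sample": ["s1", "sX"], "group": ["a", "b"]}).to_csv(
            tmp_path / "d.tsv", sep="\t", index=False)
        with pytest.raises(ExpressionIOError, match="sX"):
            exprio.load_expression(m, mp, design_path=tmp_path / "d.tsv")


class TestDesignPairing:
    def test_three_state_subject_accepted(self, paired_sim):
        """pre/case/post samples sharing a subject id pass validation."""
        es = paired_sim.expression
        subj = es.design["subject"].dropna()
        assert subj.groupby(subj).size().isin([2, 3]).all()

    def test_repeated_group_for_subject_rejected(self, noise_free_sim):
        es = noise_free_sim.expression
        design = es.design.copy()
        design.iloc[0, design.columns.get_loc("subject")] = "dup"
        design.iloc[1, design.columns.get_loc("subject")] = "dup"
        with pytest.raises(ExpressionIOError, match="dup"):
            ExpressionSet(intensities=es.intensities,
                          probeset_map=es.probeset_map, design=design)


def test_expression_round_trip(tmp_path, noise_free_sim):
    """write + load reproduces intensities, DABG, design and map."""
    from exonsplice.synthdata import write_simulation

    paths = write_simulation(noise_free_sim, tmp_path)
    es = exprio.load_expression(paths["matrix"], paths["map"],
                                dabg_path=paths["dabg"],
                                design_path=paths["design"])
    orig = noise_free_sim.expression
    assert np.allclose(es.intensities, orig.intensities, atol=1e-5)
    assert np.allclose(es.dabg, orig.dabg, atol=1e-5)
    assert (es.design["group"] == orig.design["group"]).all()
    assert (es.probeset_map["constitutive"].astype(bool)
            == orig.probeset_map["constitutive"]).all()
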