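import textwrap

import pytest

from biletree import Peak, RelativeSpectrum, Spectrum, normalize, read_mgf, write_assignments, write_mgf
from biletree.errors import MGFParseError
from biletree.tree import BinAssignment

from conftest import make_relative, make_spectrum

TWO_BLOCK_MGF = textwrap.dedent(
    """\
    BEGIN IONS
    PEPMASS=500.3040
    CHARGE=1+
    SCANS=5
    201.163 1000
    211.147 200
    END IONS
    BEGIN IONS
    TITLE=second block
    PEPMASS=498.2883 12345.0
    SCANS=9
    339.27 50
    321.26 80
    161.132 10
    END IONS
    """
)


class TestReadMGF:
    def test_scan_ids_and_fields(self, tmp_path):
        path = tmp_path / "two.mgf"
        path.write_text(TWO_BLOCK_MGF)
        spectra = read_mgf(path)
        assert [s.scan_id for s in spectra] == ["5", "9"]
        assert spectra[0].precursor_mz == pytest.approx(500.3040)
        assert spectra[0].charge == 1
        # PEPMASS intensity second field tolerated
        assert spectra[1].precursor_mz == pytest.approx(498.2883)

    def test_tic_and_sorting(self, tmp_path):
        path = tmp_path / "two.mgf"
        path.write_text(TWO_BLOCK_MGF)
        first, second = read_mgf(path)
        assert first.tic == pytest.approx(1200.0)
        # block 2 lists peaks in descending m/z; stored ascending
        mzs = [p.mz for p in second.peaks]
        assert mzs == sorted(mzs)

    def test_title_fallback_and_index_fallback(self, tmp_path):
        path = tmp_path / "fallback.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=mytitle\nPEPMASS=400.1\n100.0 1\nEND IONS\n"
            "BEGIN IONS\nPEPMASS=401.1\n100.0 1\nEND IONS\n"
        )
        spectra = read_mgf(path)
        assert spectra[0].scan_id == "mytitle"
        assert spectra[1].scan_id == "2"  # 1-based block index

    def test_missing_pepmass_names_block(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text(
            "BEGIN IONS\nPEPMASS=400.1\n100.0 1\nEND IONS\n"
            "BEGIN IONS\nSCANS=7\n100.0 1\nEND IONS\n"
        )
        with pytest.raises(MGFParseError, match="block 2"):
            read_mgf(path)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert read_mgf(path) == []

    def test_zero_intensity_peaks_dropped(self, tmp_path):
        path = tmp_path / "zero.mgf"
        path.write_text("BEGIN IONS\nPEPMASS=400.1\n100.0 0\n200.0 5\nEND IONS\n")
        (spectrum,) = read_mgf(path)
        assert [p.mz for p in spectrum.peaks] == [200.0]


class TestSpectrumModel:
    def test_duplicate_mz_merged_by_summing(self):
        s = make_spectrum([(100.0, 5.0), (100.0, 7.0), (200.0, 1.0)])
        assert [p.intensity for p in s.peaks] == [12.0, 1.0]

    def test_at_least_one_peak_required(self):
        with pytest.raises(ValueError):
            Spectrum.from_arrays("x", 400.0, [100.0], [0.0])

    def test_peak_invariants(self):
        with pytest.raises(ValueError):
            Peak(-1.0, 5.0)
        with pytest.raises(ValueError):
            Peak(100.0, -5.0)


class TestNormalize:
    @pytest.mark.parametrize(
        "intensities, expected",
        [([1000.0, 200.0], [100.0, 20.0]), ([7.0], [100.0]), ([3.0, 6.0, 12.0], [25.0, 50.0, 100.0])],
    )
    def test_base_peak_scaling(self, intensities, expected):
        peaks = [(100.0 + 10 * i, v) for i, v in enumerate(intensities)]
        rel = normalize(make_spectrum(peaks))
        assert [p.intensity for p in rel.peaks] == pytest.approx(expected)
        assert isinstance(rel, RelativeSpectrum)

    def test_idempotent(self):
        rel = normalize(make_spectrum([(100.0, 40.0), (200.0, 80.0)]))
        again = normalize(rel)
        assert [p.intensity for p in again.peaks] == [p.intensity for p in rel.peaks]


class TestMGFRoundTrip:
    def test_round_trip_fidelity(self, tmp_path):
        spectra = [
            make_spectrum([(201.163, 1000.0), (211.147, 200.0)], scan_id="5", precursor_mz=500.3040),
            make_spectrum([(161.1323, 10.5), (321.2632, 80.25)], scan_id="abc", precursor_mz=498.2883),
        ]
        path = tmp_path / "rt.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert [s.scan_id for s in back] == [s.scan_id for s in spectra]
        for a, b in zip(spectra, back):
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-6)
            for pa, pb in zip(a.peaks, b.peaks):
                assert pb.mz == pytest.approx(pa.mz, abs=1e-6)
                assert pb.intensity == pytest.approx(pa.intensity, abs=1e-6)


class TestWriteAssignments:
    def test_empty_list_gives_header_only(self, tmp_path):
        path = tmp_path / "a.tsv"
        frame = write_assignments([], path)
        assert len(frame) == 0
        assert path.read_text().splitlines()[0].split("\t")[0] == "scan_id"

    def test_unambiguous_single_row(self, tmp_path):
        a = BinAssignment("1", 500.0, "dihydroxy", ("Dihydroxy", "ketone"), "ketone",
                          False, ("ketone",), (("Dihydroxy", "ketone"),))
        frame = write_assignments([a], tmp_path / "a.tsv")
        assert len(frame) == 1
        assert frame.loc[0, "ambiguous"] == False  # noqa: E712
        assert frame.loc[0, "terminal_bin"] == "ketone"

    def test_ambiguous_one_row_per_matched_bin(self, tmp_path, dihydroxy_tree):
        from biletree import classify_spectrum

        # satisfies both sibling 12a leaves: carries both leaf marker ions
        spectrum = make_relative(
            [(482.2935, 100.0), (321.26, 50.0), (339.27, 50.0),
             (201.163, 10.0), (211.147, 2.0), (253.195, 8.0), (271.206, 8.0)]
        )
        a = classify_spectrum(spectrum, dihydroxy_tree)
        assert a.ambiguous and len(a.matched_bins) == 2
        frame = write_assignments([a], tmp_path / "a.tsv")
        assert len(frame) == 2
        assert frame["ambiguous"].all()
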