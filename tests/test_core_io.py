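"""Parcellation fixture, file readers, cohort filtering, band-pass utility."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dcctree.core_io import (
    Cohort,
    FilterThresholds,
    ParseError,
    bandpass_demean,
    filter_cohort,
    load_dmn_parcellation,
    read_phenotype,
    read_timeseries,
    write_timeseries,
    SubjectTimeSeries,
)
from .conftest import make_record

# frozen replica of the 18 DMN ROI definitions (abbrev, subsystem, x, y, z)
DMN_ROIS = [
    ("aMPFC", "core", -6, 52, -2), ("PCC", "core", -8, -56, 26),
    ("dMPFC", "dMPFC", 0, 52, 26), ("lTPJ", "dMPFC", -54, -54, 28),
    ("lLTC", "dMPFC", -60, -24, -18), ("lTempP", "dMPFC", -50, 14, -40),
    ("rTPJ", "dMPFC", 54, -54, 28), ("rLTC", "dMPFC", 60, -24, -18),
    ("rTempP", "dMPFC", 50, 14, -40), ("vMPFC", "MTL", 0, 26, -18),
    ("lpIPL", "MTL", -44, -74, 32), ("lRsp", "MTL", -14, -52, 8),
    ("lPHC", "MTL", -28, -40, -12), ("lHF+", "MTL", -22, -20, -26),
    ("rpIPL", "MTL", 44, -74, 32), ("rRsp", "MTL", 14, -52, 8),
    ("rPHC", "MTL", 28, -40, -12), ("rHF+", "MTL", 22, -20, -26),
]


class TestParcellation:
    def test_matches_frozen_roi_table_cell_by_cell(self):
        parc = load_dmn_parcellation()
        assert parc.n == 18
        for roi, (abbrev, subsystem, x, y, z) in zip(parc.rois, DMN_ROIS):
            assert roi.abbrev == abbrev
            assert roi.subsystem == subsystem
            assert (roi.mni_x, roi.mni_y, roi.mni_z) == (x, y, z)
            assert roi.radius == 10.0

    def test_named_landmarks(self):
        parc = load_dmn_parcellation()
        assert parc.rois[1].abbrev == "PCC"
        assert (parc.rois[1].mni_x, parc.rois[1].mni_y, parc.rois[1].mni_z) == (-8, -56, 26)
        assert parc.rois[0].abbrev == "aMPFC"
        assert (parc.rois[0].mni_x, parc.rois[0].mni_y, parc.rois[0].mni_z) == (-6, 52, -2)


class TestReadTimeseries:
    def test_dimensions_and_orientation(self, tmp_path, rng):
        parc = load_dmn_parcellation()
        data = rng.standard_normal((150, 18))
        path = tmp_path / "s.tsv"
        pd.DataFrame(data, columns=parc.abbrevs).to_csv(path, sep="\t", index=False)
        ts = read_timeseries(path, parc)
        assert ts.data.shape == (18, 150)
        np.testing.assert_allclose(ts.data, data.T)

    def test_column_order_invariance(self, tmp_path, rng):
        parc = load_dmn_parcellation()
        data = rng.standard_normal((50, 18))
        ordered = tmp_path / "a.tsv"
        permuted = tmp_path / "b.tsv"
        df = pd.DataFrame(data, columns=parc.abbrevs)
        df.to_csv(ordered, sep="\t", index=False)
        df[df.columns[::-1]].to_csv(permuted, sep="\t", index=False)
        np.testing.assert_array_equal(
            read_timeseries(ordered, parc).data, read_timeseries(permuted, parc).data)

    def test_missing_column_names_absent_roi(self, tmp_path, rng):
        parc = load_dmn_parcellation()
        df = pd.DataFrame(rng.standard_normal((50, 17)), columns=parc.abbrevs[:-1])
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ParseError, match="rHF"):
            read_timeseries(path, parc)

    def test_roundtrip_preserves_values(self, tmp_path, rng):
        parc = load_dmn_parcellation()
        ts = SubjectTimeSeries("s1", rng.standard_normal((18, 40)))
        path = tmp_path / "rt.tsv"
        write_timeseries(ts, path, parc)
        back = read_timeseries(path, parc)
        np.testing.assert_allclose(back.data, ts.data, rtol=1e-9)


class TestReadPhenotype:
    def _write(self, tmp_path, rows):
        path = tmp_path / "pheno.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    def _row(self, sid, group="TD", **kw):
        row = dict(subject_id=sid, group=group, age=15, sex="M", iq=100,
                   site="S1", func_mean_fd=0.1, func_perc_fd=5.0,
                   ados_total=None, ados_comm=None, ados_social=None,
                   ados_stereo_behav=None)
        row.update(kw)
        return row

    def test_valid_table(self, tmp_path):
        path = self._write(tmp_path, [self._row(f"s{i}") for i in range(6)])
        cohort = read_phenotype(path)
        assert len(cohort) == 6

    def test_duplicate_subject_rejected(self, tmp_path):
        path = self._write(tmp_path, [self._row("s1"), self._row("s1")])
        with pytest.raises(ValueError, match="duplicate"):
            read_phenotype(path)

    def test_missing_ados_is_explicit_missing(self, tmp_path):
        rows = [self._row("s1", group="ASD", ados_total=12),
                self._row("s2", group="TD")]
        cohort = read_phenotype(self._write(tmp_path, rows))
        assert cohort.records[0].ados("TOTAL") == 12
        assert cohort.records[1].ados("TOTAL") is None

    def test_out_of_range_perc_fd_rejected(self, tmp_path):
        path = self._write(tmp_path, [self._row("s1", func_perc_fd=130.0)])
        with pytest.raises(ValueError, match="func_perc_fd"):
            read_phenotype(path)


class TestFilterCohort:
    def _toy(self):
        # eleven records; exactly three violate exactly one criterion each
        good = dict(site="S1")
        records = [
            make_record("k1", "ASD", **good), make_record("k2", "ASD", **good),
            make_record("k3", "ASD", **good), make_record("k4", "ASD", **good),
            make_record("k5", "TD", **good), make_record("k6", "TD", **good),
            make_record("k7", "TD", **good), make_record("k8", "TD", **good),
            make_record("b1", "TD", func_mean_fd=0.35, **good),   # motion
            make_record("b2", "TD", func_perc_fd=40.0, **good),   # spikes
            make_record("b3", "TD", iq=60.0, **good),             # IQ
        ]
        return Cohort(records=records)

    def test_hand_enumerated_exclusions(self):
        # site S1 keeps 4 ASD + 4 TD (>3 each) after the three exclusions
        out, report = filter_cohort(self._toy(), return_report=True)
        assert sorted(out.subject_ids) == [f"k{i}" for i in range(1, 9)]
        assert report.counts() == {"missing_field": 0, "mean_fd": 1,
                                   "perc_fd": 1, "iq": 1, "site_size": 0}

    def test_disabled_thresholds_are_identity(self):
        cohort = self._toy()
        th = FilterThresholds(max_mean_fd=np.inf, max_perc_fd=np.inf,
                              min_iq=-np.inf, min_per_site_group=0)
        out = filter_cohort(cohort, th)
        assert out.subject_ids == cohort.subject_ids

    def test_site_rule_strictly_greater_than_three(self):
        # 3 ASD + 2 TD survivors at one site -> whole site dropped
        records = ([make_record(f"a{i}", "ASD", site="X") for i in range(3)]
                   + [make_record(f"t{i}", "TD", site="X") for i in range(2)])
        out = filter_cohort(Cohort(records=records))
        assert len(out) == 0

    def test_idempotent(self):
        once = filter_cohort(self._toy())
        twice = filter_cohort(once)
        assert twice.subject_ids == once.subject_ids


class TestBandpass:
    def test_output_rows_are_demeaned(self, rng):
        ts = SubjectTimeSeries("s", rng.standard_normal((3, 200)) + 5.0, tr=2.0)
        out = bandpass_demean(ts)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-10
        assert out.demeaned

    def test_passband_sinusoid_preserved(self):
        t = np.arange(400) * 2.0  # tr = 2 s
        x = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass_demean(SubjectTimeSeries("s", x[None, :], tr=2.0))
        # compare amplitude in the central portion (away from filter edges)
        amp = np.abs(out.data[0, 50:-50]).max()
        assert abs(amp - 1.0) < 0.05

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(800) * 1.0  # tr = 1 s
        x = np.sin(2 * np.pi * 0.4 * t)
        out = bandpass_demean(SubjectTimeSeries("s", x[None, :], tr=1.0),
                              low=0.01, high=0.1)
        assert np.abs(out.data[0, 200:-200]).max() < 0.1

    def test_infeasible_band_raises(self):
        ts = SubjectTimeSeries("s", np.random.default_rng(0).standard_normal((2, 100)),
                               tr=4.0)  # Nyquist 0.125 Hz
        with pytest.raises(ValueError, match="infeasible"):
            bandpass_demean(ts, low=0.01, high=0.2)
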