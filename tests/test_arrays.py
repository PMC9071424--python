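import numpy as np
import pandas as pd
import pytest

from sumoscreen import arrays, synthetic
from sumoscreen.arrays import (
    ArrayScan,
    call_hits,
    compute_m_values,
    normalize_to_controls,
    read_gpr,
    snr,
    snr_table,
    summarize_duplicates,
    write_gpr,
)
from sumoscreen.errors import DegenerateDataError, FormatError, ValidationError

from conftest import make_spot, scan_from_spots


class TestReadGpr:
    def test_four_row_fixture(self, gpr_file):
        scan = read_gpr(gpr_file, "bound")
        assert len(scan) == 4
        assert len({s.feature_id for s in scan.spots}) == 2
        assert scan.condition == "bound"

    def test_header_metadata_preserved(self, gpr_file):
        scan = read_gpr(gpr_file, "bound")
        assert scan.metadata["Type"] == "GenePix Results 3"
        assert scan.metadata["Scanner"] == "test"

    def test_missing_column_named_in_error(self, tmp_path, gpr_text):
        broken = gpr_text.replace("B median", "B mean")
        path = tmp_path / "broken.gpr"
        path.write_text(broken)
        with pytest.raises(FormatError, match="B median"):
            read_gpr(path, "bound")

    def test_empty_data_section(self, tmp_path):
        path = tmp_path / "empty.gpr"
        path.write_text(
            "ATF\t1.0\n0\t11\n"
            "Block\tRow\tColumn\tX\tY\tID\tName\tF median\tB median\tB SD\tFlags\n"
        )
        with pytest.raises(DegenerateDataError):
            read_gpr(path, "bound")

    def test_control_regex(self, tmp_path, gpr_text):
        text = gpr_text.replace("PROT00002", "CTRL_BSA")
        path = tmp_path / "ctrl.gpr"
        path.write_text(text)
        scan = read_gpr(path, "bound")
        assert sum(s.is_control for s in scan.spots) == 2

    def test_control_id_list(self, gpr_file):
        scan = read_gpr(gpr_file, "bound", control_regex=None,
                        control_ids={"FEAT00002"})
        assert [s.is_control for s in scan.spots] == [False, False, True, True]

    def test_roundtrip_through_generator(self, tmp_path):
        cfg = synthetic.ArrayConfig(seed=1, n_features=60, n_controls=6)
        bound, _, _ = synthetic.gen_array(cfg)
        path = tmp_path / "rt.gpr"
        write_gpr(bound, path)
        again = read_gpr(path, "bound")
        orig = bound.to_frame()
        back = again.to_frame()
        pd.testing.assert_frame_equal(orig, back, check_exact=False, atol=1e-9)


class TestSnr:
    def test_basic_arithmetic(self):
        assert snr(make_spot(fg=1000, bg=100, bg_sd=10)) == 90.0

    def test_zero_when_fg_equals_bg(self):
        assert snr(make_spot(fg=100, bg=100, bg_sd=10)) == 0.0

    def test_negative_allowed(self):
        assert snr(make_spot(fg=50, bg=100, bg_sd=25)) == -2.0

    def test_zero_bg_sd_uses_fallback(self):
        with pytest.warns(UserWarning):
            assert snr(make_spot(fg=110, bg=100, bg_sd=0), fallback_bg_sd=5.0) == 2.0

    def test_zero_bg_sd_no_fallback(self):
        with pytest.raises(DegenerateDataError):
            snr(make_spot(bg_sd=0))

    def test_scanwide_fallback(self):
        spots = [
            make_spot(col=1, fid="A", fg=110, bg=100, bg_sd=0),
            make_spot(col=2, fid="B", fg=110, bg=100, bg_sd=5),
            make_spot(col=3, fid="C", fg=110, bg=100, bg_sd=5),
        ]
        with pytest.warns(UserWarning):
            df = snr_table(scan_from_spots(spots))
        assert df.loc[0, "snr"] == 2.0  # fallback = median bg_sd = 5

    def test_degenerate_scan(self):
        spots = [make_spot(col=c, fid=f"F{c}", bg_sd=0) for c in (1, 2)]
        with pytest.raises(DegenerateDataError):
            snr_table(scan_from_spots(spots))


class TestNormalizeToControls:
    def _scan(self):
        # controls with S/N {4, 6} -> median 5; feature S/N 10
        return scan_from_spots([
            make_spot(col=1, fid="C1", pid="C1", control=True, fg=140, bg=100, bg_sd=10),
            make_spot(col=2, fid="C2", pid="C2", control=True, fg=160, bg=100, bg_sd=10),
            make_spot(col=3, fid="F1", pid="P1", fg=200, bg=100, bg_sd=10),
        ])

    def test_division_by_control_median(self):
        df = normalize_to_controls(self._scan())
        assert df.attrs["control_median"] == 5.0
        assert df.loc[df.feature_id == "F1", "norm_snr"].item() == 2.0

    def test_identity_at_control_median(self):
        scan = scan_from_spots([
            make_spot(col=1, fid="C1", control=True, fg=150, bg=100),
            make_spot(col=2, fid="F1", fg=150, bg=100),
        ])
        df = normalize_to_controls(scan)
        assert (df["norm_snr"] == 1.0).all()

    def test_flagged_control_excluded(self):
        # controls S/N {4, 6, 20(flagged)}; hand-recomputed median on the
        # two survivors is 5
        scan = scan_from_spots([
            make_spot(col=1, fid="C1", control=True, fg=140, bg=100),
            make_spot(col=2, fid="C2", control=True, fg=160, bg=100),
            make_spot(col=3, fid="C3", control=True, fg=300, bg=100, flag=-100),
            make_spot(col=4, fid="F1", fg=200, bg=100),
        ])
        df = normalize_to_controls(scan)
        assert df.attrs["control_median"] == 5.0

    def test_no_controls_error_mentions_override(self):
        scan = scan_from_spots([make_spot(col=c, fid=f"F{c}") for c in (1, 2)])
        with pytest.raises(ValidationError, match="override"):
            normalize_to_controls(scan)

    def test_override(self):
        scan = scan_from_spots([make_spot(col=1, fid="F1", fg=200, bg=100)])
        df = normalize_to_controls(scan, control_median_override=5.0)
        assert df["norm_snr"].item() == 2.0


class TestSummarizeDuplicates:
    def _normalized(self, values_flags):
        spots = [
            make_spot(col=i + 1, fid="F1", fg=100 + 10 * v, bg=100, flag=f)
            for i, (v, f) in enumerate(values_flags)
        ]
        spots.append(make_spot(row=9, fid="C1", control=True, fg=110, bg=100))
        return normalize_to_controls(scan_from_spots(spots), control_median_override=1.0)

    def test_mean_of_duplicates(self):
        df, dropped = summarize_duplicates(self._normalized([(2.0, 0), (4.0, 0)]))
        assert df.loc[df.feature_id == "F1", "norm_snr"].item() == pytest.approx(3.0)
        assert dropped == []

    def test_single_survivor(self):
        df, dropped = summarize_duplicates(self._normalized([(7.0, -75), (7.0, 0)]))
        row = df[df.feature_id == "F1"]
        assert row["norm_snr"].item() == pytest.approx(7.0)
        assert row["n_spots"].item() == 1

    def test_all_flagged_dropped(self):
        df, dropped = summarize_duplicates(self._normalized([(2.0, -50), (4.0, -50)]))
        assert "F1" not in set(df["feature_id"])
        assert dropped == ["F1"]


class TestComputeMValues:
    def test_identity_scans_give_zero_m(self):
        cfg = synthetic.ArrayConfig(seed=7, n_features=120, n_controls=8)
        bound, _, _ = synthetic.gen_array(cfg)
        mock = ArrayScan(spots=bound.spots, condition="mock")
        m = compute_m_values(bound, mock)
        assert np.abs(m["m_value"]).max() < 1e-9

    def test_constant_offset_absorbed_by_trend(self):
        # multiply non-control signal in the bound channel by 2^c: the loess
        # fits the constant c and residual M stays ~0
        cfg = synthetic.ArrayConfig(seed=8, n_features=100, n_controls=8,
                                    noise_sd=0.0)
        bound, _, _ = synthetic.gen_array(cfg)
        c = 1.5
        shifted = []
        for s in bound.spots:
            fg = s.fg_median
            if not s.is_control:
                fg = s.bg_median + (s.fg_median - s.bg_median) * 2.0**c
            shifted.append(make_spot(
                block=s.block_id, row=s.row, col=s.col, x=s.x, y=s.y,
                fid=s.feature_id, pid=s.protein_id, control=s.is_control,
                fg=fg, bg=s.bg_median, bg_sd=s.bg_sd, flag=s.flag))
        m = compute_m_values(ArrayScan(shifted, "bound"),
                             ArrayScan(bound.spots, "mock"))
        feats = m[~m.is_control]
        assert np.abs(feats["m_value"]).max() < 1e-6

    def test_spatial_detrending_reduces_variance(self):
        cfg = synthetic.ArrayConfig(seed=9, n_features=400, n_spikes=0,
                                    spatial_gradient=(2.0, 2.0), printtip_sd=0.6)
        bound, mock, _ = synthetic.gen_array(cfg)
        m = compute_m_values(bound, mock)
        # independent reconstruction of the raw D values
        nb, _ = summarize_duplicates(normalize_to_controls(bound))
        nm, _ = summarize_duplicates(normalize_to_controls(mock))
        merged = nb.merge(nm, on="feature_id", suffixes=("_b", "_m"))
        d = np.log2(np.maximum(merged["norm_snr_b"], 1e-6)) - np.log2(
            np.maximum(merged["norm_snr_m"], 1e-6))
        assert m["m_value"].std() < d.std()

    def test_small_printtip_group_skipped_with_warning(self):
        cfg = synthetic.ArrayConfig(seed=10, n_features=20, n_controls=2,
                                    n_blocks=8)
        bound, mock, _ = synthetic.gen_array(cfg)
        with pytest.warns(UserWarning, match="print-tip"):
            compute_m_values(bound, mock)


class TestCallHits:
    def _table(self, values, controls=None):
        controls = controls or [False] * len(values)
        return pd.DataFrame({
            "feature_id": [f"F{i}" for i in range(len(values))],
            "protein_id": [f"P{i}" for i in range(len(values))],
            "is_control": controls,
            "a_value": 0.0,
            "m_value": values,
        })

    def test_hand_arithmetic_example(self):
        # {0,0,0,10}: mean 2.5, sample SD 5, threshold 7.5 -> one hit
        calls = call_hits(self._table([0.0, 0.0, 0.0, 10.0]), k=1.0)
        assert calls.threshold == pytest.approx(7.5)
        assert calls.table["is_hit"].sum() == 1
        assert calls.table.iloc[0]["m_value"] == 10.0  # sorted descending

    def test_value_at_threshold_is_hit(self):
        t = self._table([0.0, 1.0, 2.0, 3.0])
        mu, sd = np.mean([0, 1, 2, 3]), np.std([0, 1, 2, 3], ddof=1)
        calls = call_hits(t, k=(3.0 - mu) / sd)  # threshold lands exactly on 3
        assert calls.table.set_index("protein_id").loc["P3", "is_hit"]

    def test_all_equal_no_hits(self):
        with pytest.warns(UserWarning, match="zero variance"):
            calls = call_hits(self._table([1.0, 1.0, 1.0]))
        assert calls.table["is_hit"].sum() == 0

    def test_too_few_records(self):
        with pytest.raises(ValidationError):
            call_hits(self._table([1.0]))

    def test_controls_excluded_from_population(self):
        t = self._table([0.0, 0.0, 0.0, 10.0, 100.0],
                        controls=[False, False, False, False, True])
        calls = call_hits(t, k=1.0)
        assert calls.threshold == pytest.approx(7.5)
        assert not calls.table.set_index("protein_id").loc["P4", "is_hit"]

    def test_isoform_collapsing(self):
        t = self._table([0.0, 0.0, 0.0, 10.0, 11.0])
        t.loc[3, "protein_id"] = "PX.1"
        t.loc[4, "protein_id"] = "PX.2"
        calls = call_hits(t, k=1.0)
        assert calls.unique_candidates == ["PX"]

    def test_scale_invariance_of_hit_calls(self):
        cfg = synthetic.ArrayConfig(seed=11, n_features=200, n_spikes=5,
                                    spike_effect=0.6)
        bound, mock, _ = synthetic.gen_array(cfg)

        def scaled(scan, factor):
            spots = [make_spot(
                block=s.block_id, row=s.row, col=s.col, x=s.x, y=s.y,
                fid=s.feature_id, pid=s.protein_id, control=s.is_control,
                fg=s.fg_median * factor, bg=s.bg_median * factor,
                bg_sd=s.bg_sd, flag=s.flag) for s in scan.spots]
            return ArrayScan(spots, scan.condition)

        calls1 = call_hits(compute_m_values(bound, mock))
        calls2 = call_hits(compute_m_values(scaled(bound, 3.0), scaled(mock, 3.0)))
        h1 = set(calls1.table.loc[calls1.table.is_hit, "feature_id"])
        h2 = set(calls2.table.loc[calls2.table.is_hit, "feature_id"])
        assert h1 == h2

    def test_spike_recall_on_seeded_fixture(self):
        cfg = synthetic.ArrayConfig(seed=12, n_features=500, n_spikes=8,
                                    spike_effect=0.6)  # ~4 residual SDs
        bound, mock, truth = synthetic.gen_array(cfg)
        calls = call_hits(compute_m_values(bound, mock))
        tab = calls.table.merge(truth, on="feature_id")
        assert tab.loc[tab.is_spike, "is_hit"].all()
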