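"""Biomarker panel derivation, aquatic subtyping and site summaries."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sherdmix import PipelineConfig, compute_panel, summarize_site
from sherdmix.biomarkers import classify_aquatic_subtype

from conftest import make_record


class TestComputePanel:
    def test_c18_apaa_alone_is_not_aquatic(self):
        # the C18 homologue also forms from heated terrestrial plant oils
        panel = compute_panel(make_record(abundances={"APAA_C18": 1.0}))
        assert panel.aquatic_flag is False

    def test_both_apaa_homologues_are_aquatic(self):
        panel = compute_panel(make_record(abundances={"APAA_C18": 1.0, "APAA_C20": 0.2}))
        assert panel.aquatic_flag is True

    def test_dha_alone_is_aquatic(self):
        panel = compute_panel(make_record(abundances={"DHA": 0.5}))
        assert panel.aquatic_flag is True

    def test_single_apaa_suffices_when_configured(self):
        cfg = PipelineConfig(aquatic_requires_both_apaas=False)
        panel = compute_panel(make_record(abundances={"APAA_C18": 1.0}), cfg)
        assert panel.aquatic_flag is True

    def test_ps_ratio_reaches_observed_maximum(self):
        panel = compute_panel(make_record(abundances={"C16:0": 10.7, "C18:0": 1.0}))
        assert panel.ps_ratio == pytest.approx(10.7)

    def test_ps_ratio_absent_without_stearic(self):
        assert compute_panel(make_record(abundances={"C16:0": 5.0})).ps_ratio is None
        assert (
            compute_panel(make_record(abundances={"C16:0": 5.0, "C18:0": 0.0})).ps_ratio
            is None
        )

    def test_equal_diastereomers_give_50_pct_srr(self):
        panel = compute_panel(
            make_record(abundances={"phytanic_SRR": 1.0, "phytanic_RRR": 1.0})
        )
        assert panel.pct_srr == pytest.approx(50.0)

    def test_pct_srr_absent_with_single_diastereomer(self):
        assert compute_panel(make_record(abundances={"phytanic_SRR": 1.0})).pct_srr is None

    def test_all_absent_input_yields_inert_panel(self):
        panel = compute_panel(make_record())
        assert panel.ps_ratio is None
        assert panel.pct_srr is None
        assert panel.tmtd_phytanic is None
        assert not panel.aquatic_flag
        assert panel.aquatic_subtype == "indeterminate"
        assert not (panel.maize_alkanol_flag or panel.palm_flag or panel.hopane_flag)

    @pytest.mark.parametrize(
        "abundances,expected",
        [
            # C32 above trace + two supporting even-carbon alkanols
            ({"alkanol_C32": 5.0, "alkanol_C28": 0.5, "alkanol_C30": 0.5}, True),
            # C32 above trace but only one supporting alkanol
            ({"alkanol_C32": 5.0, "alkanol_C28": 0.5}, False),
            # C32 at trace level
            ({"alkanol_C32": 0.5, "alkanol_C28": 0.5, "alkanol_C30": 0.5}, False),
            # short-chain C24/C26 do not count as support
            ({"alkanol_C32": 5.0, "alkanol_C24": 0.5, "alkanol_C26": 0.5}, False),
        ],
    )
    def test_maize_alkanol_flag(self, abundances, expected):
        cfg = PipelineConfig(alkanol_trace_threshold=1.0)
        assert compute_panel(make_record(abundances=abundances), cfg).maize_alkanol_flag is expected

    def test_palm_and_hopane_flags(self):
        cfg = PipelineConfig(palm_c12_threshold=5.0)
        high = compute_panel(make_record(abundances={"C12:0": 20.0, "hopane_C31": 1.0}), cfg)
        low = compute_panel(make_record(abundances={"C12:0": 1.0}), cfg)
        assert high.palm_flag and high.hopane_flag
        assert not (low.palm_flag or low.hopane_flag)


class TestAquaticSubtype:
    def aquatic_panel(self, **kwargs):
        panel = compute_panel(make_record(abundances={"DHA": 1.0}))
        for key, value in kwargs.items():
            setattr(panel, key, value)
        return panel

    def test_both_ratios_in_windows_is_shellfish(self, cfg):
        panel = self.aquatic_panel(pct_srr=30.0, tmtd_phytanic=0.5)
        assert classify_aquatic_subtype(panel, cfg) == "shellfish_like"

    def test_window_boundaries_included(self, cfg):
        panel = self.aquatic_panel(pct_srr=20.0, tmtd_phytanic=1.63)
        assert classify_aquatic_subtype(panel, cfg) == "shellfish_like"

    def test_outside_windows_is_fish_or_mammal(self, cfg):
        panel = self.aquatic_panel(pct_srr=80.0, tmtd_phytanic=2.0)
        assert classify_aquatic_subtype(panel, cfg) == "fish_or_mammal_like"

    def test_one_ratio_outside_suffices_for_fish(self, cfg):
        panel = self.aquatic_panel(pct_srr=80.0, tmtd_phytanic=None)
        assert classify_aquatic_subtype(panel, cfg) == "fish_or_mammal_like"

    def test_missing_ratios_are_indeterminate(self, cfg):
        panel = self.aquatic_panel(pct_srr=None, tmtd_phytanic=None)
        assert classify_aquatic_subtype(panel, cfg) == "indeterminate"

    def test_non_aquatic_never_subtyped(self, cfg):
        panel = compute_panel(make_record(abundances={"phytanic_SRR": 1.0, "phytanic_RRR": 1.0}))
        assert panel.aquatic_subtype == "indeterminate"


@given(
    a=st.floats(min_value=1e-6, max_value=1e6),
    b=st.floats(min_value=1e-6, max_value=1e6),
)
def test_pct_srr_complementarity(a, b):
    """%SRR(a, b) + %SRR(b, a) = 100 for positive diastereomer abundances."""
    pa = compute_panel(make_record(abundances={"phytanic_SRR": a, "phytanic_RRR": b}))
    pb = compute_panel(make_record(abundances={"phytanic_SRR": b, "phytanic_RRR": a}))
    assert pa.pct_srr + pb.pct_srr == pytest.approx(100.0, abs=1e-6)


def _site_fixture():
    records = []
    for i in range(10):
        records.append(
            make_record(
                f"S{i}",
                site="siteA",
                lipid_yield=20.0,
                abundances={"DHA": 1.0} if i == 0 else {},
                d13c={"C16:0": (-25.0, 0.3), "C18:0": (-27.0, 0.3)},
            )
        )
    records.append(make_record("low", site="siteA", lipid_yield=4.9))
    records.append(make_record("empty", site="siteB", lipid_yield=1.0))
    panels = {r.sample_id: compute_panel(r) for r in records}
    return records, panels


class TestSummarizeSite:
    def test_counts_percentages_and_mean_delta(self, cfg):
        records, panels = _site_fixture()
        table = summarize_site(records, panels, cfg).set_index("site")
        row = table.loc["siteA"]
        assert row["n"] == 10  # the 4.9 µg/g sherd is excluded
        assert row["aquatic_pct"] == 10
        assert row["mean_delta_18_0_16_0"] == pytest.approx(-2.0)

    def test_sub_threshold_site_keeps_blank_row(self, cfg):
        records, panels = _site_fixture()
        table = summarize_site(records, panels, cfg).set_index("site")
        row = table.loc["siteB"]
        assert row["n"] == 0
        import pandas as pd

        assert pd.isna(row["aquatic_pct"])
        assert pd.isna(row["mean_delta_18_0_16_0"])

    def test_raising_threshold_never_increases_n(self, cfg):
        import dataclasses

        records, panels = _site_fixture()
        previous = None
        for threshold in (1.0, 5.0, 10.0, 30.0, 100.0):
            c = dataclasses.replace(cfg, lipid_yield_threshold=threshold)
            n = summarize_site(records, panels, c).set_index("site").loc["siteA", "n"]
            if previous is not None:
                assert n <= previous
            previous = n

    def test_summary_invariant_to_record_order(self, cfg):
        records, panels = _site_fixture()
        forward = summarize_site(records, panels, cfg).sort_values("site").reset_index(drop=True)
        backward = summarize_site(records[::-1], panels, cfg).sort_values("site").reset_index(drop=True)
        assert forward.equals(backward)
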