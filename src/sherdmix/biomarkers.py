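"""Biomarker flags and ratios for aquatic, maize, palm and fermentation markers.

The aquatic criterion follows the convention for heated aquatic oils:
ω-(o-alkylphenyl)alkanoic acids (APAAs) with both C18 and C20 homologues,
or dihydroxy acids (DHAs). C18 APAAs alone also form from heated
terrestrial plant oils, so by default they do not trigger the flag
(configurable). Phytanic-acid diastereomers give %SRR =
100·SRR/(SRR+RRR); aquatic organisms are enriched in the SRR form, and
shellfish occupy a characteristic window of %SRR and TMTD/phytanic
ratios distinct from fish and marine mammals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import PipelineConfig
from .isotopes import delta_offset
from .types import ALKANOLS, HOPANES, SherdRecord

AQUATIC_SUBTYPES = ("fish_or_mammal_like", "shellfish_like", "indeterminate")

#: Even-carbon long-chain n-alkanols that corroborate the C32 maize marker.
_MAIZE_SUPPORT_ALKANOLS = tuple(
    a for a in ALKANOLS if a != "alkanol_C32" and int(a.rsplit("C", 1)[1]) >= 28
)


@dataclass
class BiomarkerPanel:
    """Derived per-sherd biomarker flags and ratios (absent values are None)."""

    sample_id: str
    ps_ratio: float | None = None  # palmitic/stearic abundance ratio
    pct_srr: float | None = None  # % SRR among phytanic diastereomers
    tmtd_phytanic: float | None = None  # TMTD / (SRR + RRR)
    aquatic_flag: bool = False
    aquatic_subtype: str = "indeterminate"
    maize_alkanol_flag: bool = False
    palm_flag: bool = False
    hopane_flag: bool = False
    levoglucosan_present: bool = False


def _present(record: SherdRecord, key: str) -> bool:
    value = record.abundances.get(key)
    return value is not None and value > 0


def compute_panel(record: SherdRecord, cfg: PipelineConfig | None = None) -> BiomarkerPanel:
    """Derive all biomarker flags/ratios for one sherd.

    Ratios with absent or zero denominators are absent, never infinite.
    An all-absent abundance map yields an all-absent/false panel.
    """
    cfg = cfg or PipelineConfig()
    ab = record.abundances

    ps_ratio = None
    if _present(record, "C18:0") and "C16:0" in ab:
        ps_ratio = ab["C16:0"] / ab["C18:0"]

    pct_srr = None
    tmtd_phytanic = None
    srr, rrr = ab.get("phytanic_SRR"), ab.get("phytanic_RRR")
    if srr is not None and rrr is not None and srr + rrr > 0:
        pct_srr = 100.0 * srr / (srr + rrr)
        if "TMTD" in ab:
            tmtd_phytanic = ab["TMTD"] / (srr + rrr)

    if cfg.aquatic_requires_both_apaas:
        apaa = _present(record, "APAA_C18") and _present(record, "APAA_C20")
    else:
        apaa = _present(record, "APAA_C18") or _present(record, "APAA_C20")
    aquatic_flag = apaa or _present(record, "DHA")

    c32 = ab.get("alkanol_C32")
    n_support = sum(_present(record, a) for a in _MAIZE_SUPPORT_ALKANOLS)
    maize_alkanol_flag = (
        c32 is not None and c32 > cfg.alkanol_trace_threshold and n_support >= 2
    )

    c12 = ab.get("C12:0")
    palm_flag = c12 is not None and c12 > cfg.palm_c12_threshold

    panel = BiomarkerPanel(
        sample_id=record.sample_id,
        ps_ratio=ps_ratio,
        pct_srr=pct_srr,
        tmtd_phytanic=tmtd_phytanic,
        aquatic_flag=aquatic_flag,
        maize_alkanol_flag=maize_alkanol_flag,
        palm_flag=palm_flag,
        hopane_flag=any(_present(record, h) for h in HOPANES),
        levoglucosan_present=_present(record, "levoglucosan"),
    )
    panel.aquatic_subtype = classify_aquatic_subtype(panel, cfg)
    return panel


def classify_aquatic_subtype(panel: BiomarkerPanel, cfg: PipelineConfig | None = None) -> str:
    """Subdivide aquatic sherds by the shellfish windows (closed intervals).

    shellfish_like requires both %SRR and TMTD/phytanic inside their
    windows; a single ratio present and outside its window indicates
    fish/marine-mammal character; anything else (including non-aquatic
    sherds) is indeterminate.
    """
    cfg = cfg or PipelineConfig()
    if not panel.aquatic_flag:
        return "indeterminate"
    srr_lo, srr_hi = cfg.shellfish_srr_window
    tmtd_lo, tmtd_hi = cfg.shellfish_tmtd_window
    srr_in = panel.pct_srr is not None and srr_lo <= panel.pct_srr <= srr_hi
    tmtd_in = panel.tmtd_phytanic is not None and tmtd_lo <= panel.tmtd_phytanic <= tmtd_hi
    if srr_in and tmtd_in:
        return "shellfish_like"
    srr_out = panel.pct_srr is not None and not srr_in
    tmtd_out = panel.tmtd_phytanic is not None and not tmtd_in
    if srr_out or tmtd_out:
        return "fish_or_mammal_like"
    return "indeterminate"


def summarize_site(
    records: list[SherdRecord],
    panels: dict[str, BiomarkerPanel],
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-(site, tradition) summary: n above the lipid-yield threshold,
    % with aquatic biomarkers (integer), and mean Δ13C_18:0–16:0 (1 decimal).

    Sites whose every record falls at/below the threshold keep a row with
    n = 0 and blank statistics.
    """
    cfg = cfg or PipelineConfig()
    groups: dict[tuple[str, str], list[SherdRecord]] = {}
    for r in records:
        groups.setdefault((r.site, r.tradition), []).append(r)

    rows = []
    for (site, tradition), members in groups.items():
        included = [r for r in members if r.lipid_yield > cfg.lipid_yield_threshold]
        n = len(included)
        if n == 0:
            rows.append(
                {"site": site, "tradition": tradition, "n": 0,
                 "aquatic_pct": None, "mean_delta_18_0_16_0": None}
            )
            continue
        n_aquatic = sum(
            1 for r in included
            if (p := panels.get(r.sample_id)) is not None and p.aquatic_flag
        )
        deltas = [
            d for r in included
            if (d := delta_offset(r.proxy_value("C18:0"), r.proxy_value("C16:0")))
            is not None
        ]
        rows.append(
            {
                "site": site,
                "tradition": tradition,
                "n": n,
                "aquatic_pct": int(round(100.0 * n_aquatic / n)),
                "mean_delta_18_0_16_0": round(sum(deltas) / len(deltas), 1)
                if deltas
                else None,
            }
        )
    return pd.DataFrame(rows, columns=["site", "tradition", "n", "aquatic_pct", "mean_delta_18_0_16_0"])
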