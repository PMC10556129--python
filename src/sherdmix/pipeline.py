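"""End-to-end orchestration: screen → classify → mix → summarise → contrast.

The pipeline is a pure function of (inputs, config, seed): biomarker
panels, Δ13C offsets and ellipse classifications per sherd, a Bayesian
mixing posterior for every sherd carrying at least two δ13C proxies,
per-site summaries and the between-group statistics, all written as CSV
plus a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import BiomarkerPanel, compute_panel, summarize_site
from .config import PipelineConfig
from .io import (
    read_reference_points,
    read_sherd_table,
    read_source_table,
    write_report,
)
from .isotopes import classify_against_references, delta_offset, fit_reference_ellipses
from .mixing import run_mcmc
from .stats import mann_whitney_u, pearson_r, two_sample_t
from .types import SherdRecord

logger = logging.getLogger("sherdmix")

_ISOPRENOIDS = ("TMTD", "pristanic", "phytanic_SRR", "phytanic_RRR")


def compute_deltas(records: list[SherdRecord]) -> dict[str, float]:
    """Δ13C_18:0–16:0 per sherd where both proxies were measured."""
    out = {}
    for r in records:
        d = delta_offset(r.proxy_value("C18:0"), r.proxy_value("C16:0"))
        if d is not None:
            out[r.sample_id] = d
    return out


def group_contrasts(
    records: list[SherdRecord],
    panels: dict[str, BiomarkerPanel],
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """The between-group statistics of the study design.

    Rows: isoprenoid abundance and %SRR contrasted between ceramic
    traditions (Mann–Whitney U), Δ13C_18:0–16:0 against P/S and δ13C_16:0
    against δ13C_18:1 (Pearson), δ13C_18:1 between plain and decorated
    sherds (Mann–Whitney U) and bacteriohopane frequency between plain and
    decorated sherds (t test).
    """
    cfg = cfg or PipelineConfig()
    deltas = compute_deltas(records)
    by_tradition: dict[str, list[SherdRecord]] = {}
    for r in records:
        by_tradition.setdefault(r.tradition, []).append(r)

    rows = []

    def iso_total(r: SherdRecord) -> float:
        return sum(r.abundances.get(k, 0.0) for k in _ISOPRENOIDS)

    trads = sorted(by_tradition)
    if len(trads) == 2:
        a, b = trads
        xa = [iso_total(r) for r in by_tradition[a]]
        xb = [iso_total(r) for r in by_tradition[b]]
        res = mann_whitney_u(xa, xb, report=cfg.report_u)
        rows.append(
            {"contrast": f"isoprenoid_abundance:{a}_vs_{b}", "statistic_name": "U",
             "statistic": res.statistic, "df": None, "p_value": res.p_value,
             "n1": res.n1, "n2": res.n2}
        )
        sa = [panels[r.sample_id].pct_srr for r in by_tradition[a]
              if panels.get(r.sample_id) and panels[r.sample_id].pct_srr is not None]
        sb = [panels[r.sample_id].pct_srr for r in by_tradition[b]
              if panels.get(r.sample_id) and panels[r.sample_id].pct_srr is not None]
        if sa and sb:
            res = mann_whitney_u(sa, sb, report=cfg.report_u)
            rows.append(
                {"contrast": f"pct_srr:{a}_vs_{b}", "statistic_name": "U",
                 "statistic": res.statistic, "df": None, "p_value": res.p_value,
                 "n1": res.n1, "n2": res.n2}
            )

    pairs = [
        (deltas.get(r.sample_id), panels[r.sample_id].ps_ratio)
        for r in records
        if r.sample_id in panels
    ]
    xs = np.array([d if d is not None else np.nan for d, _ in pairs])
    ys = np.array([p if p is not None else np.nan for _, p in pairs])
    if np.sum(np.isfinite(xs) & np.isfinite(ys)) >= 3:
        res = pearson_r(xs, ys)
        rows.append(
            {"contrast": "delta_18_0_16_0_vs_ps_ratio", "statistic_name": "r",
             "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
             "n1": res.n1, "n2": None}
        )

    d16 = np.array([r.proxy_value("C16:0") or np.nan for r in records], dtype=float)
    d181 = np.array([r.proxy_value("C18:1") or np.nan for r in records], dtype=float)
    if np.sum(np.isfinite(d16) & np.isfinite(d181)) >= 3:
        res = pearson_r(d16, d181)
        rows.append(
            {"contrast": "d13c_16_0_vs_d13c_18_1", "statistic_name": "r",
             "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
             "n1": res.n1, "n2": None}
        )

    plain = [r for r in records if r.decoration == "plain"]
    deco = [r for r in records if r.decoration == "decorated"]
    p181 = [v for r in plain if (v := r.proxy_value("C18:1")) is not None]
    q181 = [v for r in deco if (v := r.proxy_value("C18:1")) is not None]
    if p181 and q181:
        res = mann_whitney_u(p181, q181, report=cfg.report_u)
        rows.append(
            {"contrast": "d13c_18_1:plain_vs_decorated", "statistic_name": "U",
             "statistic": res.statistic, "df": None, "p_value": res.p_value,
             "n1": res.n1, "n2": res.n2}
        )
    if len(plain) >= 2 and len(deco) >= 2:
        hp = [float(panels[r.sample_id].hopane_flag) for r in plain if r.sample_id in panels]
        hq = [float(panels[r.sample_id].hopane_flag) for r in deco if r.sample_id in panels]
        try:
            res = two_sample_t(hp, hq)
            rows.append(
                {"contrast": "hopane_frequency:plain_vs_decorated", "statistic_name": "t",
                 "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
                 "n1": res.n1, "n2": res.n2}
            )
        except ValueError:
            pass  # degenerate: identical constant frequency in both groups
    return pd.DataFrame(
        rows, columns=["contrast", "statistic_name", "statistic", "df", "p_value", "n1", "n2"]
    )


def aquatic_frequency_by_tradition(
    records: list[SherdRecord],
    panels: dict[str, BiomarkerPanel],
    cfg: PipelineConfig | None = None,
) -> dict[str, float]:
    """% of sherds above the lipid-yield threshold carrying aquatic markers."""
    cfg = cfg or PipelineConfig()
    out = {}
    by_tradition: dict[str, list[SherdRecord]] = {}
    for r in records:
        if r.lipid_yield > cfg.lipid_yield_threshold:
            by_tradition.setdefault(r.tradition, []).append(r)
    for tradition, members in by_tradition.items():
        n = len(members)
        k = sum(1 for r in members if panels.get(r.sample_id, BiomarkerPanel(r.sample_id)).aquatic_flag)
        out[tradition] = 100.0 * k / n if n else float("nan")
    return out


def reproduce_published_contrasts(
    sherds_csv: str | Path, cfg: PipelineConfig | None = None
) -> dict:
    """Recompute the headline screening/statistics quantities from a
    per-sherd measurement table in the sherds.csv dialect.

    Returns aquatic-biomarker frequencies per tradition, the
    tradition-contrast U statistics, both Pearson correlations, the
    maximum P/S ratio, and the sample ids falling in the shellfish
    windows — the quantities a per-sherd measurement dataset pins down.
    """
    cfg = cfg or PipelineConfig()
    records = read_sherd_table(sherds_csv, cfg)
    panels = {r.sample_id: compute_panel(r, cfg) for r in records}
    contrasts = group_contrasts(records, panels, cfg)
    ps_values = [p.ps_ratio for p in panels.values() if p.ps_ratio is not None]
    shellfish = sorted(
        sid for sid, p in panels.items() if p.aquatic_subtype == "shellfish_like"
    )
    return {
        "aquatic_pct_by_tradition": aquatic_frequency_by_tradition(records, panels, cfg),
        "contrasts": contrasts,
        "max_ps_ratio": max(ps_values) if ps_values else None,
        "shellfish_window_samples": shellfish,
        "n_records": len(records),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    sherds_path: str | Path,
    sources_path: str | Path,
    reference_points_path: str | Path | None,
    config_path: str | Path | None,
    out_dir: str | Path,
    seed: int | None = None,
    mix_samples: list[str] | None = None,
) -> dict:
    """Execute the full workflow and write the report bundle to ``out_dir``.

    ``mix_samples`` optionally restricts the (slow) per-sherd Bayesian
    mixing stage to the named sample ids; by default every sherd with at
    least two δ13C proxies is modelled. On any stage error the partial
    outputs of this run are removed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig.from_yaml(config_path) if config_path else PipelineConfig()
    cfg.validate()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))

    written: list[Path] = []
    current_sample = None
    try:
        records = read_sherd_table(sherds_path, cfg)
        sources = read_source_table(sources_path)
        ellipses = {}
        if reference_points_path is not None:
            ref = read_reference_points(reference_points_path)
            ellipses = fit_reference_ellipses(
                ref, level=cfg.ellipse_level, suess_correction=cfg.suess_correction
            )

        panels = {}
        deltas = compute_deltas(records)
        classifications = {}
        posteriors = {}
        for k, r in enumerate(records):
            current_sample = r.sample_id
            panels[r.sample_id] = compute_panel(r, cfg)
            if ellipses:
                classes = classify_against_references(r, ellipses)
                if classes is not None:
                    classifications[r.sample_id] = classes
            if mix_samples is not None and r.sample_id not in mix_samples:
                continue
            observed = {p: r.d13c[p] for p in r.d13c}
            if len(observed) >= 2:
                sherd_cfg = dataclasses.replace(cfg, seed=(cfg.seed + k) % (2**31))
                posteriors[r.sample_id] = run_mcmc(sources, observed, sherd_cfg)
        current_sample = None

        report_path = out_dir / "report.csv"
        write_report(
            records, panels, posteriors, report_path,
            deltas=deltas, classifications=classifications, config=cfg, seed=cfg.seed,
        )
        written += [report_path, report_path.with_suffix(".meta.json")]

        site_path = out_dir / "site_summary.csv"
        summarize_site(records, panels, cfg).to_csv(site_path, index=False)
        written.append(site_path)

        stats_path = out_dir / "contrasts.csv"
        group_contrasts(records, panels, cfg).to_csv(stats_path, index=False)
        written.append(stats_path)

        manifest = {
            "software": "sherdmix",
            "version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "inputs": {
                "sherds": _sha256(Path(sherds_path)),
                "sources": _sha256(Path(sources_path)),
                "reference_points": _sha256(Path(reference_points_path))
                if reference_points_path
                else None,
            },
            "counts": {
                "records": len(records),
                "panels": len(panels),
                "classified": len(classifications),
                "posteriors": len(posteriors),
                "non_converged": sum(1 for p in posteriors.values() if not p.converged),
            },
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(manifest_path)
        logger.info(
            "pipeline complete: %d records, %d posteriors", len(records), len(posteriors)
        )
        return {
            "records": records,
            "panels": panels,
            "deltas": deltas,
            "classifications": classifications,
            "posteriors": posteriors,
            "manifest": manifest,
        }
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        if current_sample is not None:
            logger.error("pipeline failed while processing sample %r", current_sample)
        raise
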