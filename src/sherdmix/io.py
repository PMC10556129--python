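"""CSV readers/writers for sherd, source and reference-point tables.

One interchange dialect throughout: comma-separated UTF-8 with a header
row. Absent numeric cells stay absent (never coerced to zero), and
typographic minus signs / per-mille symbols in cells are normalised to
ASCII before parsing, since published isotope tables commonly use them.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .types import (
    COMPOUND_KEYS,
    PROXIES,
    SherdRecord,
    SourceReference,
    ValidationError,
)

#: Fixed sherd-table columns preceding the compound-abundance block.
SHERD_FIXED_COLUMNS = (
    "sample_id",
    "site",
    "tradition",
    "decoration",
    "lipid_yield_ug_g",
    "d13c_16_0",
    "d13c_16_0_sd",
    "d13c_18_0",
    "d13c_18_0_sd",
    "d13c_18_1",
    "d13c_18_1_sd",
)

_PROXY_COLUMNS = {
    "C16:0": ("d13c_16_0", "d13c_16_0_sd"),
    "C18:0": ("d13c_18_0", "d13c_18_0_sd"),
    "C18:1": ("d13c_18_1", "d13c_18_1_sd"),
}

SOURCE_COLUMNS = (
    "source",
    "fatty_acid",
    "delta_mean",
    "delta_sd",
    "conc_pct_fa",
    "fa_per_dry_weight",
)


class ParseError(ValueError):
    """Raised on malformed input tables, naming the offending row/column."""


def _normalise_cell(raw: str | None) -> str:
    if raw is None:
        return ""
    return (
        raw.replace("−", "-")  # unicode minus
        .replace("‰", "")  # per-mille sign
        .strip()
    )


def _parse_float(raw: str | None, row: int, column: str) -> float | None:
    """Parse a cell to float; empty cells mean absent. Errors cite row/column."""
    cell = _normalise_cell(raw)
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(
            f"row {row}, column {column!r}: cannot parse {raw!r} as a number"
        ) from None


def read_sherd_table(path: str | Path, cfg: PipelineConfig | None = None) -> list[SherdRecord]:
    """Read a per-sherd CSV table into validated :class:`SherdRecord` objects.

    Row order is preserved; δ13C values lacking an sd column entry get the
    configured default analytical sd. Unknown compound columns, duplicate
    sample ids and invariant violations raise :class:`ParseError`.
    """
    cfg = cfg or PipelineConfig()
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in ("sample_id", "site", "tradition", "lipid_yield_ug_g"):
            if col not in header:
                raise ParseError(f"{path.name}: missing required column {col!r}")
        compound_cols = [c for c in header if c not in SHERD_FIXED_COLUMNS]
        unknown = [c for c in compound_cols if c not in COMPOUND_KEYS]
        if unknown:
            raise ParseError(f"{path.name}: unknown compound columns {unknown}")

        records: list[SherdRecord] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):  # header is line 1
            sample_id = _normalise_cell(row.get("sample_id"))
            if not sample_id:
                raise ParseError(f"row {i}: empty sample_id")
            if sample_id in seen:
                raise ParseError(f"row {i}: duplicate sample_id {sample_id!r}")
            seen.add(sample_id)

            lipid_yield = _parse_float(row.get("lipid_yield_ug_g"), i, "lipid_yield_ug_g")
            if lipid_yield is None:
                raise ParseError(f"row {i}: lipid_yield_ug_g is required")

            d13c: dict[str, tuple[float, float]] = {}
            for proxy, (vcol, scol) in _PROXY_COLUMNS.items():
                value = _parse_float(row.get(vcol), i, vcol)
                if value is None:
                    continue
                sd = _parse_float(row.get(scol), i, scol)
                d13c[proxy] = (value, sd if sd is not None else cfg.default_d13c_sd)

            abundances: dict[str, float] = {}
            for col in compound_cols:
                value = _parse_float(row.get(col), i, col)
                if value is not None:
                    abundances[col] = value

            try:
                records.append(
                    SherdRecord(
                        sample_id=sample_id,
                        site=_normalise_cell(row.get("site")),
                        tradition=_normalise_cell(row.get("tradition")),
                        decoration=_normalise_cell(row.get("decoration")) or "unknown",
                        lipid_yield=lipid_yield,
                        abundances=abundances,
                        d13c=d13c,
                    )
                )
            except ValidationError as exc:
                raise ParseError(f"row {i}: {exc}") from exc
    return records


def write_sherd_table(records: list[SherdRecord], path: str | Path) -> None:
    """Write records in the sherds.csv dialect (numbers to 6 decimals)."""
    path = Path(path)
    columns = list(SHERD_FIXED_COLUMNS) + list(COMPOUND_KEYS)

    def fmt(x: float | None) -> str:
        return "" if x is None else f"{x:.6f}"

    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for r in records:
            row = [r.sample_id, r.site, r.tradition, r.decoration, fmt(r.lipid_yield)]
            for proxy in PROXIES:
                entry = r.d13c.get(proxy)
                row.append(fmt(entry[0] if entry else None))
                row.append(fmt(entry[1] if entry else None))
            for key in COMPOUND_KEYS:
                row.append(fmt(r.abundances.get(key)))
            writer.writerow(row)


_FA_ALIASES = {
    "C16:0": "C16:0",
    "C18:0": "C18:0",
    "C18:1": "C18:1",
    "16:0": "C16:0",
    "18:0": "C18:0",
    "18:1": "C18:1",
}


def read_source_table(path: str | Path) -> list[SourceReference]:
    """Read a long-format source reference table (one row per source x fatty acid)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in SOURCE_COLUMNS[:5]:
            if col not in header:
                raise ParseError(f"{path.name}: missing required column {col!r}")
        per_source: dict[str, dict] = {}
        order: list[str] = []
        for i, row in enumerate(reader, start=2):
            name = _normalise_cell(row.get("source"))
            fa_raw = _normalise_cell(row.get("fatty_acid"))
            fa = _FA_ALIASES.get(fa_raw)
            if fa is None:
                raise ParseError(f"row {i}: unknown fatty_acid {fa_raw!r}")
            entry = per_source.setdefault(
                name, {"delta_mean": {}, "delta_sd": {}, "conc_pct": {}, "phi": None}
            )
            if name not in order:
                order.append(name)
            if fa in entry["delta_mean"]:
                raise ParseError(f"row {i}: duplicate entry for source {name!r}, {fa}")
            for col in ("delta_mean", "delta_sd", "conc_pct_fa"):
                if _parse_float(row.get(col), i, col) is None:
                    raise ParseError(f"row {i}: column {col!r} is required")
            entry["delta_mean"][fa] = _parse_float(row.get("delta_mean"), i, "delta_mean")
            entry["delta_sd"][fa] = _parse_float(row.get("delta_sd"), i, "delta_sd")
            entry["conc_pct"][fa] = _parse_float(row.get("conc_pct_fa"), i, "conc_pct_fa")
            phi = _parse_float(row.get("fa_per_dry_weight"), i, "fa_per_dry_weight")
            if phi is not None:
                if entry["phi"] is not None and not np.isclose(entry["phi"], phi):
                    raise ParseError(
                        f"row {i}: conflicting fa_per_dry_weight for source {name!r}"
                    )
                entry["phi"] = phi

    sources = []
    for name in order:
        entry = per_source[name]
        missing = [p for p in PROXIES if p not in entry["delta_mean"]]
        if missing:
            raise ParseError(f"source {name!r}: missing fatty acid rows {missing}")
        try:
            sources.append(
                SourceReference(
                    source_name=name,
                    delta_mean=entry["delta_mean"],
                    delta_sd=entry["delta_sd"],
                    conc_pct=entry["conc_pct"],
                    fa_per_dry_weight=entry["phi"] if entry["phi"] is not None else 1.0,
                )
            )
        except ValidationError as exc:
            raise ParseError(str(exc)) from exc
    return sources


def write_source_table(sources: list[SourceReference], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SOURCE_COLUMNS)
        for s in sources:
            for fa in PROXIES:
                writer.writerow(
                    [
                        s.source_name,
                        fa,
                        f"{s.delta_mean[fa]:.6f}",
                        f"{s.delta_sd[fa]:.6f}",
                        f"{s.conc_pct[fa]:.6f}",
                        f"{s.fa_per_dry_weight:.6f}",
                    ]
                )


def read_reference_points(path: str | Path) -> pd.DataFrame:
    """Read reference-fat scatter points: columns class, d13c_16_0, d13c_18_0."""
    df = pd.read_csv(path, encoding="utf-8")
    required = {"class", "d13c_16_0", "d13c_18_0"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"reference points table missing columns {sorted(missing)}")
    for col in ("d13c_16_0", "d13c_18_0"):
        df[col] = [
            _parse_float(str(v) if not pd.isna(v) else None, i + 2, col)
            for i, v in enumerate(df[col])
        ]
        if df[col].isna().any():
            raise ParseError(f"reference points: empty cells in {col}")
    return df


def write_report(
    records,
    panels,
    posteriors,
    path: str | Path,
    *,
    deltas=None,
    classifications=None,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    extra_metadata: dict | None = None,
) -> None:
    """Write the per-sherd report CSV plus a JSON run-metadata document.

    ``panels``/``posteriors``/``deltas``/``classifications`` are mappings
    keyed by sample_id; entries may be missing for any sherd, in which case
    the corresponding columns stay blank. Re-running with identical inputs
    and seed reproduces byte-identical CSV content.
    """
    from . import __version__

    path = Path(path)
    panels = panels or {}
    posteriors = posteriors or {}
    deltas = deltas or {}
    classifications = classifications or {}

    source_names: list[str] = []
    for post in posteriors.values():
        for name in post.source_names:
            if name not in source_names:
                source_names.append(name)

    def fmt(x) -> str:
        if x is None or (isinstance(x, float) and not np.isfinite(x)):
            return ""
        if isinstance(x, bool):
            return str(x).lower()
        if isinstance(x, float):
            return f"{x:.6f}"
        return str(x)

    columns = [
        "sample_id",
        "site",
        "tradition",
        "decoration",
        "lipid_yield_ug_g",
        "d13c_16_0",
        "d13c_18_0",
        "d13c_18_1",
        "delta_18_0_16_0",
        "ps_ratio",
        "pct_srr",
        "tmtd_phytanic",
        "aquatic_flag",
        "aquatic_subtype",
        "maize_alkanol_flag",
        "palm_flag",
        "hopane_flag",
        "levoglucosan_present",
        "reference_classes",
    ]
    for name in source_names:
        columns += [f"post_mean_{name}", f"post_q2_5_{name}", f"post_q97_5_{name}"]

    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for r in records:
            panel = panels.get(r.sample_id)
            post = posteriors.get(r.sample_id)
            classes = classifications.get(r.sample_id)
            row = [
                r.sample_id,
                r.site,
                r.tradition,
                r.decoration,
                fmt(r.lipid_yield),
                fmt(r.proxy_value("C16:0")),
                fmt(r.proxy_value("C18:0")),
                fmt(r.proxy_value("C18:1")),
                fmt(deltas.get(r.sample_id)),
            ]
            if panel is None:
                row += [""] * 9
            else:
                row += [
                    fmt(panel.ps_ratio),
                    fmt(panel.pct_srr),
                    fmt(panel.tmtd_phytanic),
                    fmt(panel.aquatic_flag),
                    panel.aquatic_subtype,
                    fmt(panel.maize_alkanol_flag),
                    fmt(panel.palm_flag),
                    fmt(panel.hopane_flag),
                    fmt(panel.levoglucosan_present),
                ]
            row.append("|".join(sorted(classes)) if classes else "")
            for name in source_names:
                if post is None or name not in post.source_names:
                    row += ["", "", ""]
                else:
                    k = post.source_names.index(name)
                    row += [fmt(post.mean[k]), fmt(post.q2_5[k]), fmt(post.q97_5[k])]
            writer.writerow(row)

    metadata = {
        "software": "sherdmix",
        "version": __version__,
        "seed": seed,
        "config": (config or PipelineConfig()).to_dict(),
        "n_records": len(list(records)),
        "n_posteriors": len(posteriors),
    }
    if extra_metadata:
        metadata.update(extra_metadata)
    path.with_suffix(".meta.json").write_text(json.dumps(metadata, indent=2, sort_keys=True))
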