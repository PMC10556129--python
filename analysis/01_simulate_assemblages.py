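"""Generate the two synthetic pottery assemblages used by the downstream steps.

Writes, per archetype (a marine/C3-leaning coastal tradition of 55 sherds
and a maize-leaning tradition of 154 sherds): the sherd table, the
ground-truth composition table, the source reference table and the
reference-fat scatter points, all under results/synthetic/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from sherdmix import preset_scenarios, simulate_sherds, synthetic_reference_points
from sherdmix.io import write_sherd_table, write_source_table

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "synthetic")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    presets = preset_scenarios(seed=args.seed)
    for name, preset in presets.items():
        records, truth = simulate_sherds(preset)
        write_sherd_table(records, args.out / f"{name}_sherds.csv")
        truth.to_csv(args.out / f"{name}_truth.csv", index=False)
        print(f"{name}: {len(records)} sherds ({preset.tradition})")

    write_source_table(presets["guarani_like"].sources, args.out / "sources.csv")
    synthetic_reference_points(seed=args.seed).to_csv(
        args.out / "reference_points.csv", index=False
    )
    print(f"wrote source table and reference points to {args.out}")


if __name__ == "__main__":
    main()
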