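"""Regenerate the default precision calibration table shipped with the package.

Usage: python scripts/build_calibration.py [--seed 42]

Fits the monotone (score, p-value) -> precision table on the synthetic
labeled alignment set and writes src/gluefinder/data/calibration.json.
"""

import argparse
from pathlib import Path

from gluefinder.fixtures import make_calibration_set
from gluefinder.glue_screen import CalibrationTable


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parent.parent
        / "src/gluefinder/data/calibration.json",
    )
    args = parser.parse_args()
    scores, ps, labels, _ = make_calibration_set(seed=args.seed)
    table = CalibrationTable.from_labeled(scores, ps, labels)
    table.to_json(args.out)
    print(f"wrote {args.out}: {table.values.shape[0]}x{table.values.shape[1]} bins")


if __name__ == "__main__":
    main()
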