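#!/usr/bin/env python
"""Calculated [M-H]- m/z values for the isolated tetramic acids.

The C20 compound (BE-54476-A) and its +CH2 homolog (BE-54476-B), printed to
the 4-decimal precision used for high-resolution ESI-MS "calcd" values.
"""

from pathlib import Path

import pandas as pd

from osmacnet.formula_mass import monoisotopic_mass, mz_deprotonated

ROOT = Path(__file__).resolve().parents[1]

COMPOUNDS = [
    ("BE-54476-A", "C20H29NO5"),
    ("BE-54476-B", "C21H31NO5"),
]


def main() -> None:
    rows = [
        (name, formula, round(monoisotopic_mass(formula), 6), round(mz_deprotonated(formula), 4))
        for name, formula in COMPOUNDS
    ]
    df = pd.DataFrame(rows, columns=["compound", "neutral_formula", "monoisotopic_mass", "mh_minus_mz"])
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    df.to_csv(outdir / "06_calcd_masses.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
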