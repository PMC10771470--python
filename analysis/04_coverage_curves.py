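#!/usr/bin/env python
"""Combinatorial coverage curves: how many media (or regulators) are enough.

Enumerates every subset of fermentation media and of activators and reports
the mean +/- SD share of the maximal metabolite and scaffold space each
subset size recovers — the diminishing-returns curves behind choosing a
cost-effective screening design.
"""

from pathlib import Path

import pandas as pd

from osmacnet.chemspace import coverage_curve
from osmacnet.pipeline import analyze
from osmacnet.synthetic_data import GeneratorParams, generate_study

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    params = GeneratorParams(seed=SEED)
    study = generate_study(params)
    res = analyze(study.spectra, study.metadata)
    mat, meta = res.yield_matrix, study.metadata
    scaffold_of = {n: sid for n, (sid, _) in res.scaffolds.membership().items()}

    frames = []
    for cond_name, key in (("media", "media_id"), ("regulator", "activator")):
        conds = sorted({getattr(m, key) for m in meta.values() if getattr(m, key) != "WT"})
        met_sets, scaf_sets = {}, {}
        for c in conds:
            cols = [e for e in mat.columns if getattr(meta[e], key) == c]
            det = mat[cols].max(axis=1) > 0
            met_sets[c] = set(mat.index[det])
            scaf_sets[c] = {scaffold_of[m] for m in met_sets[c]}
        for level, sets in (("metabolite", met_sets), ("scaffold", scaf_sets)):
            curve = coverage_curve(sets, level=level)
            df = curve.as_frame()
            df.insert(0, "condition", cond_name)
            frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    out.to_csv(outdir / "04_coverage_curves.csv", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
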