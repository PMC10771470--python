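"""Differential bioactivity scoring and heat-map palette mapping.

Each extract is screened in six assays — A549 (human lung carcinoma
cytotoxicity), SA (S. aureus), EA (K. aerogenes), PA (P. aeruginosa),
ACB (A. baumannii), AF (A. fumigatus) — read out as % growth inhibition.
For every (strain, activator) combination the representative value is the
highest % inhibition over all its clones and media; the Difference is that
value minus the parent strain's highest % inhibition over all media.
Differences map onto a three-set-point palette (dark grey at -100, white at
0, an assay-specific colour at +100, linear RGB interpolation, clamped
beyond +/-100).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from matplotlib.colors import to_rgb

from osmacnet.msio import ExtractMeta

ASSAYS = ("A549", "SA", "EA", "PA", "ACB", "AF")

#: Assay endpoint colours at +100 Difference.
ASSAY_COLORS: dict[str, str] = {
    "A549": "brown",
    "SA": "red",
    "EA": "purple",
    "PA": "blue",
    "ACB": "green",
    "AF": "orange",
}

DARK_GREY = (0.3, 0.3, 0.3)
WHITE = (1.0, 1.0, 1.0)


class MissingNativeReferenceError(KeyError):
    """A mutant combination has no wild-type extracts to difference against."""


def differential_bioactivity(
    assay_table: pd.DataFrame, metadata: Mapping[str, ExtractMeta]
) -> pd.DataFrame:
    """Difference map: rows (strain, activator), columns assays.

    ``assay_table`` is indexed by extract_id with one column per assay
    (% inhibition; values beyond [0, 100] are allowed).  For each non-WT
    (strain, activator) combination and assay:
    Difference = max over the combination's clones x media
               - max over the parent strain's native extracts x media.
    """
    unknown = [c for c in assay_table.columns if c not in ASSAYS]
    if unknown:
        raise ValueError(f"unknown assay columns: {unknown}")
    extracts = [e for e in assay_table.index if e in metadata]
    native_max: dict[str, pd.Series] = {}
    combos: dict[tuple[str, str], list[str]] = {}
    for e in extracts:
        m = metadata[e]
        if m.is_wildtype:
            prev = native_max.get(m.strain_id)
            row = assay_table.loc[e]
            native_max[m.strain_id] = row if prev is None else np.maximum(prev, row)
        else:
            combos.setdefault((m.strain_id, m.activator), []).append(e)
    rows = []
    index = []
    for (strain, activator), es in sorted(combos.items()):
        if strain not in native_max:
            raise MissingNativeReferenceError(
                f"no native (WT) assay values for strain {strain}"
            )
        mutant_max = assay_table.loc[es].max(axis=0)
        rows.append(mutant_max - native_max[strain])
        index.append((strain, activator))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["strain_id", "activator"])
    )


def palette_map(difference: float, assay: str) -> tuple[float, float, float]:
    """Map a Difference to an RGB colour on the -100..+100 palette.

    Piecewise-linear in RGB between dark grey (-100), white (0) and the
    assay's endpoint colour (+100); values beyond the range clamp to the
    endpoints.
    """
    if assay not in ASSAY_COLORS:
        raise ValueError(f"unknown assay {assay!r}")
    d = float(np.clip(difference, -100.0, 100.0))
    if d >= 0:
        lo, hi, t = WHITE, to_rgb(ASSAY_COLORS[assay]), d / 100.0
    else:
        lo, hi, t = WHITE, DARK_GREY, -d / 100.0
    return tuple(float((1 - t) * a + t * b) for a, b in zip(lo, hi))


def render_heatmap(diff_map: pd.DataFrame) -> np.ndarray:
    """Difference map as an (n_rows, n_assays, 3) RGB image array."""
    img = np.empty((len(diff_map), len(diff_map.columns), 3))
    for i, (_, row) in enumerate(diff_map.iterrows()):
        for j, assay in enumerate(diff_map.columns):
            img[i, j] = palette_map(row[assay], assay)
    return img
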