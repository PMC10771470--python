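"""Unique-metabolite accounting: consolidation, yields, provenance, fold
changes, per-extract perturbation flags, and combinatorial coverage curves.

MS/MS scans of the same compound recur across extracts; they are consolidated
into *unique metabolites* by greedy centroid clustering under a precursor-mass
(0.02 Da) and retention-time (0.4 min) tolerance.  A metabolite's *yield* in
an extract is the highest total ion current (TIC) among its member scans from
that extract — TIC as a proxy for production level.  Group-level yields take
the max over media within a strain then over strains within the group, which
algebraically equals the flat max over all the group's extracts.

Provenance splits metabolites into native-only / activated-only / both, with
mutant-over-wildtype fold changes (and a binned distribution) on the shared
set.  Coverage curves enumerate every subset of conditions (media or
regulators) and report the mean and population SD of the percentage of the
maximal observed item set that each subset size recovers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from osmacnet.msio import ExtractMeta, Spectrum

DEFAULT_MZ_TOL = 0.02
DEFAULT_RT_TOL = 0.4

#: Fold-change histogram bins: <1x, [1,2)x, [2,3)x, [3,4)x, >=4x.
DEFAULT_FOLD_BINS = (1.0, 2.0, 3.0, 4.0)
FOLD_BIN_LABELS = ("<1", "1-2", "2-3", "3-4", ">=4")

MAX_COVERAGE_CONDITIONS = 8


class UndefinedFoldChangeError(ValueError):
    """Fold change requested for a metabolite with zero wild-type yield."""


@dataclass
class UniqueMetabolite:
    metabolite_id: str
    mean_precursor_mz: float
    mean_rt: float
    member_spectra: list[str]
    representative_spectrum: Spectrum

    def __len__(self) -> int:
        return len(self.member_spectra)


def consolidate(
    spectra: Sequence[Spectrum],
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> list[UniqueMetabolite]:
    """Greedy TIC-ordered centroid clustering of spectra into unique metabolites.

    Spectra are processed in descending TIC (ties by spectrum id); each joins
    the earliest-founded metabolite whose running mean precursor m/z and RT
    are both within tolerance, else founds a new one.  Means update
    incrementally, so every spectrum ends within tolerance of the mean at the
    moment it joined.  The representative spectrum is the member with the
    highest TIC.
    """
    order = sorted(range(len(spectra)), key=lambda i: (-spectra[i].tic, spectra[i].spectrum_id))
    means_mz = np.empty(0)
    means_rt = np.empty(0)
    counts = np.empty(0)
    members: list[list[int]] = []
    for idx in order:
        s = spectra[idx]
        if means_mz.size:
            ok = (np.abs(means_mz - s.precursor_mz) <= mz_tol) & (
                np.abs(means_rt - s.rt) <= rt_tol
            )
            hits = np.nonzero(ok)[0]
        else:
            hits = np.empty(0, dtype=int)
        if hits.size:
            j = int(hits[0])  # earliest-founded metabolite
            counts[j] += 1
            means_mz[j] += (s.precursor_mz - means_mz[j]) / counts[j]
            means_rt[j] += (s.rt - means_rt[j]) / counts[j]
            members[j].append(idx)
        else:
            means_mz = np.append(means_mz, s.precursor_mz)
            means_rt = np.append(means_rt, s.rt)
            counts = np.append(counts, 1.0)
            members.append([idx])
    out: list[UniqueMetabolite] = []
    for j, idxs in enumerate(members):
        rep = max((spectra[i] for i in idxs), key=lambda s: (s.tic, s.spectrum_id))
        out.append(
            UniqueMetabolite(
                metabolite_id=f"M{j:05d}",
                mean_precursor_mz=float(means_mz[j]),
                mean_rt=float(means_rt[j]),
                member_spectra=[spectra[i].spectrum_id for i in idxs],
                representative_spectrum=rep,
            )
        )
    return out


def build_yield_matrix(
    metabolites: Sequence[UniqueMetabolite], spectra: Sequence[Spectrum]
) -> pd.DataFrame:
    """Metabolite x extract yield matrix: highest member TIC per extract, 0 if absent."""
    by_id = {s.spectrum_id: s for s in spectra}
    extracts = sorted({s.extract_id for s in spectra if s.extract_id is not None})
    mat = pd.DataFrame(
        0.0, index=[m.metabolite_id for m in metabolites], columns=extracts
    )
    for m in metabolites:
        for sid in m.member_spectra:
            s = by_id[sid]
            if s.extract_id is None:
                continue
            if s.tic > mat.at[m.metabolite_id, s.extract_id]:
                mat.at[m.metabolite_id, s.extract_id] = s.tic
    return mat


def _select_extracts(
    matrix: pd.DataFrame,
    metadata: Mapping[str, ExtractMeta],
    group: str | Callable[[ExtractMeta], bool],
) -> list[str]:
    if callable(group):
        pred = group
    elif group == "wildtype":
        pred = lambda m: m.is_wildtype
    elif group == "mutant":
        pred = lambda m: not m.is_wildtype
    else:
        raise ValueError(f"unknown group {group!r}")
    return [e for e in matrix.columns if e in metadata and pred(metadata[e])]


def group_yield(
    matrix: pd.DataFrame,
    metadata: Mapping[str, ExtractMeta],
    group: str | Callable[[ExtractMeta], bool],
) -> pd.Series:
    """Representative per-metabolite yield of a group of extracts.

    Max over media within each strain, then max over strains — which equals
    the flat max over all extracts of the group.
    """
    cols = _select_extracts(matrix, metadata, group)
    if not cols:
        raise ValueError("group selects no extracts")
    return matrix[cols].max(axis=1)


def fold_change(mutant_yield: float, wildtype_yield: float) -> float:
    """Mutant-group yield over wild-type-group yield."""
    if wildtype_yield <= 0:
        raise UndefinedFoldChangeError(
            "wild-type yield is 0; metabolite belongs in the activated-only class"
        )
    return mutant_yield / wildtype_yield


def bin_fold_changes(
    fold_changes: Mapping[str, float], bin_edges: Sequence[float] = DEFAULT_FOLD_BINS
) -> dict[str, int]:
    """Histogram of fold changes over unit-width bins with an open top bin."""
    labels = ["<" + _fmt(bin_edges[0])]
    labels += [f"{_fmt(lo)}-{_fmt(hi)}" for lo, hi in zip(bin_edges[:-1], bin_edges[1:])]
    labels += [">=" + _fmt(bin_edges[-1])]
    counts = dict.fromkeys(labels, 0)
    for v in fold_changes.values():
        k = int(np.searchsorted(bin_edges, v, side="right"))
        counts[labels[k]] += 1
    return counts


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


@dataclass
class ProvenanceReport:
    """Partition of detected metabolites by producing group, with fold changes."""

    native_only: frozenset[str]
    activated_only: frozenset[str]
    both: frozenset[str]
    fold_changes: dict[str, float]
    distribution: dict[str, int]

    @property
    def n_detected(self) -> int:
        return len(self.native_only) + len(self.activated_only) + len(self.both)


def classify_provenance(
    matrix: pd.DataFrame,
    metadata: Mapping[str, ExtractMeta],
    detection_threshold: float = 0.0,
    bin_edges: Sequence[float] = DEFAULT_FOLD_BINS,
) -> ProvenanceReport:
    """Split metabolites into native-only / activated-only / both and bin fold changes.

    A metabolite is detected in a group when some extract of the group has
    yield strictly above ``detection_threshold`` (default 0: any nonzero
    yield counts).  Fold changes are computed on the "both" set only.
    """
    if detection_threshold < 0:
        raise ValueError("detection_threshold must be >= 0")
    wt_cols = _select_extracts(matrix, metadata, "wildtype")
    mu_cols = _select_extracts(matrix, metadata, "mutant")
    wt_max = matrix[wt_cols].max(axis=1) if wt_cols else pd.Series(0.0, index=matrix.index)
    mu_max = matrix[mu_cols].max(axis=1) if mu_cols else pd.Series(0.0, index=matrix.index)
    in_wt = wt_max > detection_threshold
    in_mu = mu_max > detection_threshold
    native_only = frozenset(matrix.index[in_wt & ~in_mu])
    activated_only = frozenset(matrix.index[~in_wt & in_mu])
    both = frozenset(matrix.index[in_wt & in_mu])
    fcs = {m: fold_change(float(mu_max[m]), float(wt_max[m])) for m in sorted(both)}
    return ProvenanceReport(
        native_only=native_only,
        activated_only=activated_only,
        both=both,
        fold_changes=fcs,
        distribution=bin_fold_changes(fcs, bin_edges),
    )


def compare_extract(
    matrix: pd.DataFrame,
    mutant_extract: str,
    native_extract: str,
    metadata: Mapping[str, ExtractMeta],
    detection_threshold: float = 0.0,
) -> bool:
    """True iff the mutant extract shows any new or upregulated metabolite
    over the parent-strain extract fermented in the same medium.

    "New" means detected in the mutant but not the native extract; "upregulated"
    means a shared metabolite with extract-level yield ratio strictly > 1.
    """
    mm, nm = metadata[mutant_extract], metadata[native_extract]
    if mm.media_id != nm.media_id or mm.strain_id != nm.strain_id:
        raise ValueError(
            f"extracts {mutant_extract} and {native_extract} differ in strain or media"
        )
    mu = matrix[mutant_extract]
    na = matrix[native_extract]
    new = ((mu > detection_threshold) & (na <= detection_threshold)).any()
    shared = (mu > detection_threshold) & (na > detection_threshold)
    upreg = (mu[shared] > na[shared]).any()
    return bool(new or upreg)


@dataclass
class CoverageCurve:
    """Mean +/- SD accessible-space coverage versus condition-subset size."""

    level: str
    points: dict[int, tuple[float, float, int]]  # k -> (mean %, population SD %, n subsets)
    reference_max: int

    def as_frame(self) -> pd.DataFrame:
        rows = [
            (self.level, k, mean, sd, n) for k, (mean, sd, n) in sorted(self.points.items())
        ]
        return pd.DataFrame(rows, columns=["level", "k", "mean_pct", "sd_pct", "n_subsets"])


def coverage_curve(
    condition_sets: Mapping[str, Iterable[str]], level: str = "metabolite"
) -> CoverageCurve:
    """Exact combinatorial coverage curve over all C(n, k) condition subsets.

    Coverage of a subset is the size of the union of its item sets relative
    to the union over all conditions, in percent.  Mean and *population* SD
    are reported per subset size (every subset is enumerated — a census, not
    a sample).
    """
    if not condition_sets:
        raise ValueError("no conditions given")
    if len(condition_sets) > MAX_COVERAGE_CONDITIONS:
        raise ValueError(
            f"exact subset enumeration supports at most {MAX_COVERAGE_CONDITIONS} conditions"
        )
    sets = {c: frozenset(v) for c, v in condition_sets.items()}
    full = frozenset().union(*sets.values())
    if not full:
        raise ValueError("union of all condition item-sets is empty")
    names = sorted(sets)
    points: dict[int, tuple[float, float, int]] = {}
    for k in range(1, len(names) + 1):
        covs = [
            100.0 * len(frozenset().union(*(sets[c] for c in combo))) / len(full)
            for combo in itertools.combinations(names, k)
        ]
        arr = np.asarray(covs)
        points[k] = (float(arr.mean()), float(arr.std(ddof=0)), len(covs))
    return CoverageCurve(level=level, points=points, reference_max=len(full))


def write_provenance(report: ProvenanceReport, path: str | Path) -> None:
    rows = []
    for m in sorted(report.native_only):
        rows.append((m, "native_only", ""))
    for m in sorted(report.activated_only):
        rows.append((m, "activated_only", ""))
    for m in sorted(report.both):
        rows.append((m, "both", report.fold_changes[m]))
    pd.DataFrame(rows, columns=["metabolite_id", "provenance", "fold_change"]).to_csv(
        path, index=False
    )
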