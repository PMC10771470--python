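"""Pairwise spectral similarity: the (modified) cosine score.

Fragment peaks of two spectra are matched one-to-one within a tolerance,
either directly (|mzA - mzB| <= tol) or, when shifting is allowed, offset by
the precursor mass difference (|mzA - mzB - (precA - precB)| <= tol), which
is what lets structural analogs score highly ("modified cosine").  Peak
intensities are power-weighted (sqrt by default, the classical-networking
convention) and the score is the matched weighted dot product over the
product of Euclidean norms, so identical spectra score exactly 1.

Matching is greedy in descending weighted-intensity product — the standard
practical algorithm — with deterministic tie-breaks; :func:`exact_cosine_score`
solves the same matching as an exact linear assignment problem and serves as
an independent optimality oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from osmacnet.msio import Spectrum

logger = logging.getLogger(__name__)

DIRECT = "direct"
SHIFTED = "shifted"


@dataclass(frozen=True)
class SimilarityParams:
    precursor_tol_da: float = 0.02
    fragment_tol_da: float = 0.02
    intensity_power: float = 0.5
    allow_shift: bool = True

    def __post_init__(self) -> None:
        if self.precursor_tol_da <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.intensity_power <= 1):
            raise ValueError("intensity_power must be in (0, 1]")


@dataclass
class PeakMatchSet:
    """One-to-one matched peak pairs between two spectra.

    ``pairs[k] = (index in A, index in B, kind)`` with kind ``direct`` or
    ``shifted``; ``contributions[k]`` is the weighted-intensity product the
    pair adds to the unnormalised score.
    """

    pairs: list[tuple[int, int, str]] = field(default_factory=list)
    contributions: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def total(self) -> float:
        return float(sum(self.contributions))


def _weighted(spectrum: Spectrum, power: float) -> np.ndarray:
    return spectrum.intensity**power


def _candidate_pairs(
    a: Spectrum, b: Spectrum, params: SimilarityParams
) -> list[tuple[int, int, str, float]]:
    """All (i, j, kind, contribution) pairs within tolerance, deduplicated.

    When a pair qualifies both directly and via the precursor shift it is
    kept once, labelled direct.
    """
    wa = _weighted(a, params.intensity_power)
    wb = _weighted(b, params.intensity_power)
    shifts = [(0.0, DIRECT)]
    if params.allow_shift:
        delta = a.precursor_mz - b.precursor_mz
        if abs(delta) > params.fragment_tol_da:
            shifts.append((delta, SHIFTED))
    seen: dict[tuple[int, int], int] = {}
    out: list[tuple[int, int, str, float]] = []
    for offset, kind in shifts:
        # |mzA - mzB - offset| <= tol, vectorised over the outer product
        diff = np.abs(a.mz[:, None] - b.mz[None, :] - offset)
        ii, jj = np.nonzero(diff <= params.fragment_tol_da)
        for i, j in zip(ii.tolist(), jj.tolist()):
            if (i, j) in seen:
                continue
            seen[(i, j)] = len(out)
            out.append((i, j, kind, float(wa[i] * wb[j])))
    return out


def _canonical_order(a: Spectrum, b: Spectrum) -> tuple[Spectrum, Spectrum, bool]:
    """Deterministic argument ordering so tie-breaks are symmetric in (a, b)."""
    ka = (a.precursor_mz, len(a), a.tic, a.spectrum_id)
    kb = (b.precursor_mz, len(b), b.tic, b.spectrum_id)
    if kb < ka:
        return b, a, True
    return a, b, False


def match_peaks(a: Spectrum, b: Spectrum, params: SimilarityParams = SimilarityParams()) -> PeakMatchSet:
    """Greedy one-to-one peak matching by descending weighted-intensity product.

    Ties are broken by lower m/z in A then lower m/z in B; arguments are put
    in a canonical order first so the result is symmetric.  Empty spectra
    yield an empty match set.
    """
    if len(a) == 0 or len(b) == 0:
        return PeakMatchSet()
    a0, b0, swapped = _canonical_order(a, b)
    cands = _candidate_pairs(a0, b0, params)
    cands.sort(key=lambda c: (-c[3], a0.mz[c[0]], b0.mz[c[1]]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    result = PeakMatchSet()
    for i, j, kind, contrib in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        if swapped:
            result.pairs.append((j, i, kind))
        else:
            result.pairs.append((i, j, kind))
        result.contributions.append(contrib)
    return result


def _norm(spectrum: Spectrum, power: float) -> float:
    w = _weighted(spectrum, power)
    return float(np.sqrt(np.sum(w * w)))


def cosine_score(
    a: Spectrum, b: Spectrum, params: SimilarityParams = SimilarityParams()
) -> tuple[float, int]:
    """Modified cosine score and matched-peak count for a spectrum pair.

    Returns ``(score, n_matched)`` with score in [0, 1]; a zero-norm (empty)
    spectrum scores 0 with a warning rather than an error.
    """
    na, nb = _norm(a, params.intensity_power), _norm(b, params.intensity_power)
    if na == 0.0 or nb == 0.0:
        logger.warning(
            "cosine_score: zero-norm spectrum (%s vs %s)", a.spectrum_id, b.spectrum_id
        )
        return 0.0, 0
    matches = match_peaks(a, b, params)
    return matches.total / (na * nb), len(matches)


def exact_cosine_score(
    a: Spectrum, b: Spectrum, params: SimilarityParams = SimilarityParams()
) -> tuple[float, int]:
    """Optimal one-to-one matching score via exact linear assignment.

    Independent of the greedy path: the candidate pairs form a weight matrix
    (ineligible pairs weigh 0) whose maximum-weight assignment is solved with
    :func:`scipy.optimize.linear_sum_assignment`.  Used as an optimality
    oracle for :func:`cosine_score`.
    """
    na, nb = _norm(a, params.intensity_power), _norm(b, params.intensity_power)
    if na == 0.0 or nb == 0.0:
        return 0.0, 0
    cands = _candidate_pairs(a, b, params)
    if not cands:
        return 0.0, 0
    w = np.zeros((len(a), len(b)))
    for i, j, _kind, contrib in cands:
        w[i, j] = max(w[i, j], contrib)
    rows, cols = linear_sum_assignment(w, maximize=True)
    picked = w[rows, cols]
    n_matched = int(np.count_nonzero(picked > 0))
    return float(picked.sum()) / (na * nb), n_matched
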