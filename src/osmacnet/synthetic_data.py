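"""Ground-truthed synthetic study generator.

Emulates the strain x activator x media screening design end-to-end so every
pipeline stage can be exercised and scored against a known answer:

* **Scaffold-structured spectra** — each scaffold has a backbone of shared
  fragment ions; its analogs (CH2-like homologs) shift the high-mass suffix
  of the backbone by the analog's mass offset and add a few low-intensity
  analog-specific fragments.  Within-scaffold pairs therefore share the full
  backbone (direct + precursor-shifted matches) while distinct scaffolds
  share no fragments, so default networking recovers the scaffolds exactly.
* **Sparse production** — each metabolite is produced by a few strains in a
  metabolite-specific subset of media.  Metabolites are programmed as
  native-only (lost on activation), activated-only (new on activation), or
  produced by both, with mutant yields multiplied by log-normal upregulation
  factors.
* **Noise** — spectrum-level log-normal intensity noise of a chosen CV, and
  retention-time / precursor jitter truncated at half the consolidation
  tolerances.
* **Bioactivity** — designated activation-gained metabolites carry assay
  potencies, so activator strains gain % inhibition over their parents.

Numerical safeguards: fragment m/z values live on a 0.05 Da grid (so the
0.02 Da tolerance can never half-match), within-scaffold backbone spacing is
kept >= 17.05 Da and analog shifts move a mass-ordered suffix, which together
guarantee at most 6 backbone peaks in any +/-50 Da window — the windowed
top-6 filter can then never delete a backbone fragment (analog-specific
peaks are strictly less intense).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from osmacnet.bioactivity import ASSAYS
from osmacnet.msio import ExtractMeta, Spectrum, write_metadata, write_mgf

GRID = 0.05  # Da; all fragment and precursor m/z are multiples of this


def _snap(x: float) -> float:
    return round(round(x / GRID) * GRID, 2)


@dataclass(frozen=True)
class GeneratorParams:
    """Study-design and noise parameters of the synthetic generator.

    Defaults program the study conditions the pipeline is validated against:
    104 metabolites (26 scaffolds x 4 analogs) split into 50 shared, 5
    native-only and 49 activation-only — an activated/native expansion ratio
    of (50+49)/(50+5) = 1.8 — screened over 6 strains x 3 activators x
    3 media with 2 mutant clones each.
    """

    n_scaffolds: int = 26
    analogs_per_scaffold: int = 4
    backbone_fragments: int = 10
    analog_specific_fragments: int = 3
    analog_offset_da: float = 14.05  # grid-aligned CH2-homolog step
    shifted_fraction: float = 0.5  # mass-suffix share of backbone that shifts

    n_both: int = 50
    n_native_only: int = 5
    n_activated_only: int = 49

    strains: tuple[str, ...] = ("S01", "S02", "S03", "S04", "S05", "S06")
    activators: tuple[str, ...] = ("AdpA", "Crp", "SarA")
    media: tuple[str, ...] = ("CA02LB", "CA07LB", "CA08LB")
    clones_per_mutant: int = 2
    producers_per_metabolite: int = 2

    production_prob: float = 0.9
    upregulation_median: float = 2.0
    upregulation_sigma: float = 0.8

    intensity_noise_cv: float = 0.1
    rt_jitter_sd_min: float = 0.1  # truncated at 2 SD = half the 0.4 min tolerance
    precursor_jitter_sd_da: float = 0.005  # truncated at 2 SD = half the 0.02 Da tolerance

    n_active_metabolites: int = 10
    potency_range: tuple[float, float] = (40.0, 90.0)
    assay_baseline_max: float = 15.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone_fragments < 8:
            raise ValueError("backbone_fragments must be >= 8 so analog pairs exceed the matched-peak threshold")
        if not (0 <= self.production_prob <= 1):
            raise ValueError("production_prob must be in [0, 1]")
        if self.intensity_noise_cv < 0 or self.rt_jitter_sd_min < 0 or self.precursor_jitter_sd_da < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.analog_offset_da <= 0 or abs(self.analog_offset_da / GRID - round(self.analog_offset_da / GRID)) > 1e-9:
            raise ValueError("analog_offset_da must be a positive multiple of the 0.05 Da grid")
        total = self.n_both + self.n_native_only + self.n_activated_only
        if total > self.n_scaffolds * self.analogs_per_scaffold:
            raise ValueError(
                f"{total} programmed metabolites exceed the {self.n_scaffolds * self.analogs_per_scaffold} generated templates"
            )
        if self.producers_per_metabolite > len(self.strains):
            raise ValueError("producers_per_metabolite exceeds the strain count")

    @property
    def programmed_expansion_ratio(self) -> float:
        """Programmed activated/native unique-metabolite ratio."""
        return (self.n_both + self.n_activated_only) / (self.n_both + self.n_native_only)


@dataclass
class MetaboliteTemplate:
    metabolite_id: str
    scaffold_id: str
    precursor_mz: float
    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def to_spectrum(self, spectrum_id: str, extract_id: str | None = None) -> Spectrum:
        return Spectrum(
            spectrum_id=spectrum_id,
            precursor_mz=self.precursor_mz,
            rt=self.rt,
            mz=self.mz.copy(),
            intensity=self.intensity.copy(),
            extract_id=extract_id,
        )


@dataclass
class GroundTruth:
    """Programmed answers the pipeline is scored against."""

    scaffold_of: dict[str, str]
    provenance: dict[str, list[str]]  # native_only / activated_only / both
    fold_changes: dict[str, float]  # true group-level fold change, "both" only
    media_sets: dict[str, list[str]]  # media -> detected metabolite ids
    regulator_sets: dict[str, list[str]]  # activator -> detected metabolite ids
    spectrum_metabolite: dict[str, str]  # emitted spectrum id -> metabolite id
    true_yields: pd.DataFrame | None = None  # metabolite x extract, noiseless
    true_differences: pd.DataFrame | None = None
    params: dict | None = None

    @property
    def expansion_ratio(self) -> float:
        """Realized activated/native unique-metabolite ratio."""
        n_act = len(self.provenance["both"]) + len(self.provenance["activated_only"])
        n_nat = len(self.provenance["both"]) + len(self.provenance["native_only"])
        return n_act / n_nat

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.params,
            "scaffold_of": self.scaffold_of,
            "provenance": self.provenance,
            "fold_changes": self.fold_changes,
            "media_sets": self.media_sets,
            "regulator_sets": self.regulator_sets,
            "spectrum_metabolite": self.spectrum_metabolite,
            "expansion_ratio": self.expansion_ratio,
        }
        if self.true_yields is not None:
            payload["true_yields"] = {
                m: {e: y for e, y in row.items() if y > 0}
                for m, row in self.true_yields.iterrows()
            }
        if self.true_differences is not None:
            td = self.true_differences
            payload["true_differences"] = {
                f"{strain}|{act}": row.to_dict() for (strain, act), row in td.iterrows()
            }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class StudyData:
    spectra: list[Spectrum]
    metadata: dict[str, ExtractMeta]
    assay_table: pd.DataFrame
    ground_truth: GroundTruth


def generate_scaffold_library(
    params: GeneratorParams, rng: np.random.Generator | None = None
) -> tuple[list[MetaboliteTemplate], GroundTruth]:
    """Generate scaffold-structured spectrum templates with known scaffold truth.

    Each scaffold: a backbone of ``backbone_fragments`` grid-aligned fragments
    spaced >= 17.05 Da with a shared intensity profile; each analog shifts the
    top ``shifted_fraction`` of the backbone (by mass) by its offset, adds
    ``analog_specific_fragments`` unique low-intensity fragments, and offsets
    the precursor accordingly.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    used: set[float] = set()

    def claim(pos: float) -> float:
        pos = _snap(pos)
        while pos in used:
            pos = _snap(pos + GRID)
        used.add(pos)
        return pos

    templates: list[MetaboliteTemplate] = []
    scaffold_of: dict[str, str] = {}
    span = 350.0 / max(params.n_scaffolds, 1)
    n_shift = max(1, int(round(params.shifted_fraction * params.backbone_fragments)))
    for s in range(params.n_scaffolds):
        scaffold_id = f"SC{s:03d}"
        base_precursor = _snap(600.0 + s * span + rng.uniform(0.0, min(span, 5.0)))
        # backbone: sequential positions with >= 17.05 Da gaps, globally unique
        pos = _snap(rng.uniform(100.0, 140.0))
        backbone = []
        for _ in range(params.backbone_fragments):
            pos = claim(pos)
            backbone.append(pos)
            pos = pos + _snap(rng.uniform(17.05, 26.0))
        backbone_arr = np.array(backbone)
        profile = rng.uniform(5e4, 5e5, size=params.backbone_fragments)
        for a in range(params.analogs_per_scaffold):
            offset = a * params.analog_offset_da
            mz = backbone_arr.copy()
            mz[-n_shift:] = np.round(mz[-n_shift:] + offset, 2)
            inten = profile * np.exp(rng.normal(0.0, 0.15, size=profile.size))
            spec_mz = [claim(rng.uniform(100.0, 560.0)) for _ in range(params.analog_specific_fragments)]
            spec_int = rng.uniform(2e3, 2e4, size=params.analog_specific_fragments)
            all_mz = np.concatenate([mz, np.array(spec_mz)])
            all_int = np.concatenate([inten, spec_int])
            order = np.argsort(all_mz)
            mid = f"GT{s:03d}_{a}"
            rt = float(rng.uniform(0.5, 7.5))
            templates.append(
                MetaboliteTemplate(
                    metabolite_id=mid,
                    scaffold_id=scaffold_id,
                    precursor_mz=_snap(base_precursor + offset),
                    rt=rt,
                    mz=all_mz[order],
                    intensity=all_int[order],
                )
            )
            scaffold_of[mid] = scaffold_id
    # keep (precursor, RT) pairs of distinct metabolites separable at the
    # consolidation tolerances even after jitter
    for i, t in enumerate(templates):
        for _ in range(100):
            clash = any(
                abs(u.precursor_mz - t.precursor_mz) <= 3 * 0.02 and abs(u.rt - t.rt) <= 3 * 0.4
                for u in templates[:i]
            )
            if not clash:
                break
            t.rt = float(rng.uniform(0.5, 7.5))
    truth = GroundTruth(
        scaffold_of=scaffold_of,
        provenance={"native_only": [], "activated_only": [], "both": []},
        fold_changes={},
        media_sets={},
        regulator_sets={},
        spectrum_metabolite={},
        params=asdict(params),
    )
    return templates, truth


def _truncated_normal(rng: np.random.Generator, sd: float, clip: float) -> float:
    if sd == 0:
        return 0.0
    return float(np.clip(rng.normal(0.0, sd), -clip, clip))


def generate_study(params: GeneratorParams = GeneratorParams()) -> StudyData:
    """Generate a full synthetic screening study with ground truth.

    Returns emitted spectra (one MS/MS scan per realized production event),
    extract metadata, a bioactivity table, and the programmed answers.
    """
    rng = np.random.default_rng(params.seed)
    templates, truth = generate_scaffold_library(params, rng)

    # ---- extract design ---------------------------------------------------
    metadata: dict[str, ExtractMeta] = {}
    for si, strain in enumerate(params.strains):
        origin = "marine" if si % 2 else "terrestrial"
        for media in params.media:
            wt_id = f"{strain}_WT_{media}"
            metadata[wt_id] = ExtractMeta(wt_id, strain, "WT", media, f"{strain}_parent", origin)
            for act in params.activators:
                for clone in range(1, params.clones_per_mutant + 1):
                    eid = f"{strain}_{act}_c{clone}_{media}"
                    metadata[eid] = ExtractMeta(eid, strain, act, media, f"{strain}_{act}_c{clone}", origin)
    extract_ids = sorted(metadata)

    # ---- programme metabolite classes and production rules ----------------
    n_programmed = params.n_both + params.n_native_only + params.n_activated_only
    chosen = rng.permutation(len(templates))[:n_programmed]
    classes: dict[str, str] = {}
    for k, ti in enumerate(chosen):
        mid = templates[ti].metabolite_id
        if k < params.n_both:
            classes[mid] = "both"
        elif k < params.n_both + params.n_native_only:
            classes[mid] = "native_only"
        else:
            classes[mid] = "activated_only"
    by_id = {t.metabolite_id: t for t in templates}
    producers: dict[str, list[str]] = {}
    media_sets: dict[str, list[str]] = {}
    trigger: dict[str, str] = {}
    for mid in sorted(classes):
        producers[mid] = sorted(
            rng.choice(params.strains, size=params.producers_per_metabolite, replace=False)
        )
        n_media = int(rng.integers(1, len(params.media) + 1))
        media_sets[mid] = sorted(rng.choice(params.media, size=n_media, replace=False))
        trigger[mid] = str(rng.choice(params.activators))
    upreg: dict[tuple[str, str, str], float] = {}
    for mid in sorted(classes):
        if classes[mid] != "both":
            continue
        for strain in producers[mid]:
            for act in params.activators:
                upreg[(mid, strain, act)] = float(
                    np.exp(rng.normal(np.log(params.upregulation_median), params.upregulation_sigma))
                )

    # ---- realize production events ----------------------------------------
    true_yields = pd.DataFrame(0.0, index=sorted(classes), columns=extract_ids)
    for eid in extract_ids:
        m = metadata[eid]
        for mid in sorted(classes):
            if m.strain_id not in producers[mid] or m.media_id not in media_sets[mid]:
                continue
            cls = classes[mid]
            if cls == "native_only" and not m.is_wildtype:
                continue
            if cls == "activated_only" and (m.is_wildtype or m.activator != trigger[mid]):
                continue
            if rng.random() > params.production_prob:
                continue
            factor = 1.0
            if cls == "both" and not m.is_wildtype:
                factor = upreg[(mid, m.strain_id, m.activator)]
            true_yields.at[mid, eid] = by_id[mid].tic * factor

    # ---- emit noisy spectra ------------------------------------------------
    sigma = np.sqrt(np.log1p(params.intensity_noise_cv**2))
    spectra: list[Spectrum] = []
    for eid in extract_ids:
        seq = 0
        col = true_yields[eid]
        for mid in col.index[col > 0]:
            t = by_id[mid]
            scale = float(col[mid]) / t.tic
            noise = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
            sid = f"{eid}::{seq:04d}"
            seq += 1
            spectra.append(
                Spectrum(
                    spectrum_id=sid,
                    precursor_mz=t.precursor_mz
                    + _truncated_normal(rng, params.precursor_jitter_sd_da, 2 * params.precursor_jitter_sd_da),
                    rt=t.rt + _truncated_normal(rng, params.rt_jitter_sd_min, 2 * params.rt_jitter_sd_min),
                    mz=t.mz.copy(),
                    intensity=t.intensity * scale * noise,
                    extract_id=eid,
                )
            )
            truth.spectrum_metabolite[sid] = mid

    # ---- ground-truth provenance / fold changes / coverage sets ------------
    wt_cols = [e for e in extract_ids if metadata[e].is_wildtype]
    mu_cols = [e for e in extract_ids if not metadata[e].is_wildtype]
    wt_max = true_yields[wt_cols].max(axis=1)
    mu_max = true_yields[mu_cols].max(axis=1)
    for mid in true_yields.index:
        in_wt, in_mu = wt_max[mid] > 0, mu_max[mid] > 0
        if in_wt and in_mu:
            truth.provenance["both"].append(mid)
            truth.fold_changes[mid] = float(mu_max[mid] / wt_max[mid])
        elif in_wt:
            truth.provenance["native_only"].append(mid)
        elif in_mu:
            truth.provenance["activated_only"].append(mid)
    for media in params.media:
        cols = [e for e in extract_ids if metadata[e].media_id == media]
        det = true_yields[cols].max(axis=1) > 0
        truth.media_sets[media] = sorted(true_yields.index[det])
    for act in params.activators:
        cols = [e for e in extract_ids if metadata[e].activator == act]
        det = true_yields[cols].max(axis=1) > 0
        truth.regulator_sets[act] = sorted(true_yields.index[det])
    truth.true_yields = true_yields

    # ---- bioactivity table --------------------------------------------------
    gained = truth.provenance["activated_only"]
    n_active = min(params.n_active_metabolites, len(gained))
    active_ids = sorted(rng.choice(gained, size=n_active, replace=False)) if n_active else []
    potency = {
        mid: (str(rng.choice(ASSAYS)), float(rng.uniform(*params.potency_range)))
        for mid in active_ids
    }
    assay = pd.DataFrame(
        rng.uniform(0.0, params.assay_baseline_max, size=(len(extract_ids), len(ASSAYS))),
        index=extract_ids,
        columns=list(ASSAYS),
    )
    for mid, (assay_name, pot) in potency.items():
        present = true_yields.loc[mid] > 0
        assay.loc[present[present].index, assay_name] += pot
    # true differences from the same max-over-clones/media definition
    rows, index = [], []
    native_max = {
        strain: assay.loc[[e for e in wt_cols if metadata[e].strain_id == strain]].max(axis=0)
        for strain in params.strains
    }
    for strain in params.strains:
        for act in params.activators:
            es = [e for e in mu_cols if metadata[e].strain_id == strain and metadata[e].activator == act]
            rows.append(assay.loc[es].max(axis=0) - native_max[strain])
            index.append((strain, act))
    truth.true_differences = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["strain_id", "activator"])
    )

    return StudyData(spectra=spectra, metadata=metadata, assay_table=assay, ground_truth=truth)


def write_study(study: StudyData, outdir: str | Path) -> None:
    """Write the study in the formats the pipeline consumes.

    ``extracts/<extract_id>.mgf`` per extract, ``metadata.csv``,
    ``bioactivity.csv`` and ``ground_truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "extracts").mkdir(parents=True, exist_ok=True)
    by_extract: dict[str, list[Spectrum]] = {}
    for s in study.spectra:
        by_extract.setdefault(s.extract_id, []).append(s)
    for eid in sorted(study.metadata):
        write_mgf(by_extract.get(eid, []), outdir / "extracts" / f"{eid}.mgf")
    write_metadata(
        [study.metadata[e] for e in sorted(study.metadata)], outdir / "metadata.csv"
    )
    study.assay_table.rename_axis("extract_id").to_csv(outdir / "bioactivity.csv")
    study.ground_truth.to_json(outdir / "ground_truth.json")
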