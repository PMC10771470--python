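"""Configuration-driven orchestration of the full chemical-space analysis.

Stages, in the order the networking workflow applies them: global background
correction -> per-spectrum GNPS-style peak filtering -> consolidation into
unique metabolites -> modified-cosine molecular networking of representative
spectra (mutual top-k) -> scaffold enumeration -> yield matrix -> provenance
and fold-change statistics -> per-extract perturbation flags -> combinatorial
media-coverage curves -> differential bioactivity.  Every stage is a pure
function of the configuration and inputs; the summary report echoes all
effective parameters and the counts dropped at each filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from osmacnet import chemspace, network as netmod
from osmacnet.bioactivity import differential_bioactivity
from osmacnet.msio import (
    ExtractMeta,
    Spectrum,
    background_filter,
    read_metadata,
    read_mgf,
    write_mgf,
)
from osmacnet.simscore import SimilarityParams
from osmacnet.specproc import FilterParams, preprocess

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters, defaulting to the networking workflow's values."""

    input_dir: str | None = None
    output_dir: str | None = None

    background_min_intensity: float = 1000.0
    precursor_window_da: float = 17.0
    window_top_k: int = 6
    window_half_width_da: float = 50.0

    precursor_tol_da: float = 0.02
    fragment_tol_da: float = 0.02
    intensity_power: float = 0.5
    allow_shift: bool = True

    min_cosine: float = 0.7
    min_matched: int = 6
    top_k: int = 10

    consolidation_mz_tol: float = 0.02
    consolidation_rt_tol: float = 0.4
    detection_threshold: float = 0.0
    fold_bins: tuple[float, ...] = chemspace.DEFAULT_FOLD_BINS

    seed: int = 0

    @property
    def filter_params(self) -> FilterParams:
        return FilterParams(self.precursor_window_da, self.window_top_k, self.window_half_width_da)

    @property
    def sim_params(self) -> SimilarityParams:
        return SimilarityParams(
            self.precursor_tol_da, self.fragment_tol_da, self.intensity_power, self.allow_shift
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "fold_bins" in data:
            data["fold_bins"] = tuple(data["fold_bins"])
        return cls(**data)


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    config: PipelineConfig
    spectra: list[Spectrum]
    metabolites: list[chemspace.UniqueMetabolite]
    yield_matrix: pd.DataFrame
    network: netmod.MolecularNetwork
    scaffolds: netmod.ScaffoldSet
    provenance: chemspace.ProvenanceReport
    unperturbed_extracts: list[str]
    n_mutant_extracts: int
    coverage: dict[str, chemspace.CoverageCurve]
    difference_map: pd.DataFrame | None
    filter_log: dict[str, int]

    def metabolite_of_spectrum(self) -> dict[str, str]:
        return {
            sid: m.metabolite_id for m in self.metabolites for sid in m.member_spectra
        }

    def summary(self) -> dict:
        report = {
            "n_spectra": len(self.spectra),
            "n_unique_metabolites": len(self.metabolites),
            "n_clusters": len(self.scaffolds.clusters),
            "n_orphans": len(self.scaffolds.orphans),
            "n_scaffolds": self.scaffolds.n_scaffolds,
            "provenance": {
                "native_only": len(self.provenance.native_only),
                "activated_only": len(self.provenance.activated_only),
                "both": len(self.provenance.both),
            },
            "fold_change_distribution": self.provenance.distribution,
            "max_fold_change": max(self.provenance.fold_changes.values(), default=None),
            "n_mutant_extracts": self.n_mutant_extracts,
            "n_unperturbed_extracts": len(self.unperturbed_extracts),
            "unperturbed_extracts": sorted(self.unperturbed_extracts),
            "coverage": {
                level: {
                    str(k): {"mean_pct": mean, "sd_pct": sd, "n_subsets": n}
                    for k, (mean, sd, n) in sorted(curve.points.items())
                }
                for level, curve in self.coverage.items()
            },
            "filter_log": self.filter_log,
            "parameters": asdict(self.config),
        }
        if self.difference_map is not None:
            report["difference_map"] = {
                f"{strain}|{act}": row.to_dict()
                for (strain, act), row in self.difference_map.iterrows()
            }
        return report


def analyze(
    spectra: Sequence[Spectrum],
    metadata: Mapping[str, ExtractMeta],
    assay_table: pd.DataFrame | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full analysis on in-memory spectra and metadata."""
    missing = sorted({s.extract_id for s in spectra if s.extract_id not in metadata})
    if missing:
        raise ValueError(f"spectra reference extracts missing from metadata: {missing[:5]}")

    filter_log: dict[str, int] = {"input_spectra": len(spectra)}
    corrected = background_filter(spectra, config.background_min_intensity)
    filter_log["after_background_filter"] = len(corrected)
    fp = config.filter_params
    filtered = [s for s in (preprocess(s, fp) for s in corrected) if len(s) > 0]
    filter_log["after_peak_filters"] = len(filtered)

    metabolites = chemspace.consolidate(
        filtered, config.consolidation_mz_tol, config.consolidation_rt_tol
    )
    matrix = chemspace.build_yield_matrix(metabolites, filtered)

    strains_with_mutants = {m.strain_id for m in metadata.values() if not m.is_wildtype}
    strains_with_wt = {m.strain_id for m in metadata.values() if m.is_wildtype}
    orphan_strains = sorted(strains_with_mutants - strains_with_wt)
    if orphan_strains:
        raise ValueError(f"no wild-type extracts for strains: {orphan_strains}")

    nodes = {m.metabolite_id: m.representative_spectrum for m in metabolites}
    net = netmod.build_network(
        nodes, config.sim_params, config.min_cosine, config.min_matched, config.top_k
    )
    scaffolds = netmod.extract_scaffolds(net)

    provenance = chemspace.classify_provenance(
        matrix, metadata, config.detection_threshold, config.fold_bins
    )

    # per-extract perturbation flags: mutant extract vs the parent strain in
    # the same medium (max profile over WT replicates)
    unperturbed: list[str] = []
    n_mutant = 0
    wt_by_key: dict[tuple[str, str], list[str]] = {}
    for eid in matrix.columns:
        m = metadata[eid]
        if m.is_wildtype:
            wt_by_key.setdefault((m.strain_id, m.media_id), []).append(eid)
    for eid in matrix.columns:
        m = metadata[eid]
        if m.is_wildtype:
            continue
        n_mutant += 1
        natives = wt_by_key.get((m.strain_id, m.media_id), [])
        if not natives:
            continue
        thr = config.detection_threshold
        mu = matrix[eid]
        na = matrix[natives].max(axis=1)
        new = ((mu > thr) & (na <= thr)).any()
        shared = (mu > thr) & (na > thr)
        upreg = (mu[shared] > na[shared]).any()
        if not (new or upreg):
            unperturbed.append(eid)

    thr = config.detection_threshold
    scaffold_of = {n: sid for n, (sid, _kind) in scaffolds.membership().items()}
    media_ids = sorted({m.media_id for m in metadata.values()})
    media_met: dict[str, set[str]] = {}
    media_scaf: dict[str, set[str]] = {}
    for media in media_ids:
        cols = [e for e in matrix.columns if metadata[e].media_id == media]
        det = matrix[cols].max(axis=1) > thr if cols else pd.Series(False, index=matrix.index)
        mets = set(matrix.index[det])
        media_met[media] = mets
        media_scaf[media] = {scaffold_of[m] for m in mets}
    coverage = {
        "metabolite": chemspace.coverage_curve(media_met, level="metabolite"),
        "scaffold": chemspace.coverage_curve(media_scaf, level="scaffold"),
    }

    diff_map = None
    if assay_table is not None:
        diff_map = differential_bioactivity(assay_table, metadata)

    return PipelineResult(
        config=config,
        spectra=filtered,
        metabolites=metabolites,
        yield_matrix=matrix,
        network=net,
        scaffolds=scaffolds,
        provenance=provenance,
        unperturbed_extracts=unperturbed,
        n_mutant_extracts=n_mutant,
        coverage=coverage,
        difference_map=diff_map,
        filter_log=filter_log,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the analysis from files on disk and write all artifacts.

    ``config.input_dir`` must contain MGF files (searched recursively) and a
    ``metadata.csv``; an optional ``bioactivity.csv`` enables the differential
    bioactivity stage.  Artifacts are written under ``config.output_dir``.
    """
    if config.input_dir is None:
        raise ValueError("input_dir is required")
    indir = Path(config.input_dir)
    mgf_files = sorted(indir.rglob("*.mgf"))
    if not mgf_files:
        raise ValueError(f"no MGF files found under {indir}")
    spectra: list[Spectrum] = []
    for f in mgf_files:
        spectra.extend(read_mgf(f))
    metadata = read_metadata(indir / "metadata.csv")
    assay_path = indir / "bioactivity.csv"
    assay = pd.read_csv(assay_path, index_col="extract_id") if assay_path.exists() else None

    result = analyze(spectra, metadata, assay, config)

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mgf(result.spectra, outdir / "filtered.mgf")
        result.yield_matrix.rename_axis("metabolite_id").to_csv(outdir / "yield_matrix.csv")
        netmod.write_edge_list(result.network, outdir / "edges.csv")
        netmod.write_graphml(result.network, outdir / "network.graphml")
        netmod.write_scaffold_membership(result.scaffolds, outdir / "scaffolds.csv")
        chemspace.write_provenance(result.provenance, outdir / "provenance.csv")
        pd.concat([c.as_frame() for c in result.coverage.values()]).to_csv(
            outdir / "coverage.csv", index=False
        )
        if result.difference_map is not None:
            result.difference_map.to_csv(outdir / "difference_map.csv")
        (outdir / "report.json").write_text(json.dumps(result.summary(), indent=1))
        logger.info("pipeline artifacts written to %s", outdir)
    return result
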