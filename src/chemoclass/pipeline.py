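"""End-to-end orchestration: extract -> train -> classify -> statistics.

A :class:`RunConfig` carries every tolerance and threshold of the workflow
with the study defaults; :func:`run` executes the stages over a directory
of mzML files (or pre-extracted spectra), writing each stage's tables under
stage-named subdirectories together with a manifest of input hashes and
per-stage counts so a run is reproducible and each stage re-runnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import chemodiversity, classification, eco_stats, tree_comparison
from .classification import classify_all, train, unmatched_ids
from .ontology import Ontology, ReferenceSpectrum, build_split, read_library_msp
from .spectra_io import (MergedSpectrum, filter_spectra, merge_spectra,
                         read_mzml, read_msp, write_msp)

logger = logging.getLogger("chemoclass")


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of a pipeline run (study defaults)."""

    mz_tol: float = 0.01            # Da, precursor merge tolerance
    rt_tol: float = 5.0             # s, retention-time merge tolerance
    mass_min: float = 50.0          # Da, evaluated precursor-mass window
    mass_max: float = 1000.0
    rt_min: float = 10.0            # s, evaluated retention-time window
    rt_max: float = 1020.0
    bin_width: float = 0.01         # Da, fragment bin width
    abundance_threshold: float = 100.0
    alpha: float = 0.05             # retained-assignment p-value cutoff
    n_perm: int = 999               # permutations for Mantel/envfit
    linkage: str = "average"
    seed: int = 42

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_raw(path: Path) -> dict[str, list]:
    """MS2 spectra per sample from an mzML file or an MSP of raw spectra.

    MSP entries are grouped into samples by the ``sample::scan`` id
    convention (the whole file is one sample when ids carry no prefix).
    """
    if path.suffix.lower() == ".msp":
        spectra, _ = read_msp(path)
        by_sample: dict[str, list] = {}
        for s in spectra:
            sample = s.id.split("::", 1)[0] if "::" in s.id else path.stem
            by_sample.setdefault(sample, []).append(s)
        return by_sample
    return {path.stem: read_mzml(path)}


def extract_stage(config: RunConfig, input_paths: Sequence[Path],
                  out_dir: Path) -> tuple[list[MergedSpectrum], dict]:
    """Read, merge and window-filter the MS2 spectra of every sample."""
    out_dir.mkdir(parents=True, exist_ok=True)
    all_kept: list[MergedSpectrum] = []
    n_parsed = n_merged = 0
    for path in input_paths:
        for sample, raw in sorted(_load_raw(path).items()):
            merged = merge_spectra(raw, mz_tol=config.mz_tol, rt_tol=config.rt_tol,
                                   bin_width=config.bin_width)
            kept = filter_spectra(merged, (config.mass_min, config.mass_max),
                                  (config.rt_min, config.rt_max))
            n_parsed += len(raw)
            n_merged += len(merged)
            all_kept.extend(kept)
    write_msp(all_kept, out_dir / "spectra.msp")
    counts = {"parsed": n_parsed, "merged": n_merged, "filtered": len(all_kept)}
    logger.info("extract: %s", counts)
    return all_kept, counts


def train_stage(config: RunConfig, library: Sequence[ReferenceSpectrum],
                ontology: Ontology, out_dir: Path
                ) -> list[classification.ClassifierModel]:
    """Train one classifier per ontology class and serialize the models."""
    out_dir.mkdir(parents=True, exist_ok=True)
    models = []
    for cid in ontology.ids:
        split = build_split(library, cid, ontology)
        model = train(split, w=config.bin_width,
                      threshold=config.abundance_threshold)
        classification.save_model(model, out_dir / f"{cid}.json")
        models.append(model)
    return models


def run(config: RunConfig, mzml_dir: str | Path, library_msp: str | Path,
        ontology_tsv: str | Path | None, metadata_tsv: str | Path,
        out_dir: str | Path, phylo_newick: str | Path | None = None,
        eco_tsv: str | Path | None = None) -> Path:
    """Execute the full workflow and write stage outputs plus a manifest.

    Stages: extract (mzML -> merged, filtered MSP), train (library ->
    per-class models), classify (assignments TSV), diversity (count
    matrices, diversity indices, sunburst counts), trees (Bray-Curtis,
    chemotaxonomic dendrogram, comparison metrics when a phylogeny is
    given), ecostats (variation partitioning, optional envfit).  Any stage
    failure raises with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    if ontology_tsv is None:
        from .ontology import study_ontology
        ontology = study_ontology()
        ontology_inputs: list[Path] = []
    else:
        from .ontology import load_ontology
        ontology = load_ontology(ontology_tsv)
        ontology_inputs = [Path(ontology_tsv)]

    mzml_paths = (sorted(Path(mzml_dir).glob("*.mzML"))
                  + sorted(Path(mzml_dir).glob("*.mzml"))
                  + sorted(Path(mzml_dir).glob("*.msp")))
    mzml_paths = [p for p in mzml_paths if p.name != "library.msp"]
    if not mzml_paths:
        raise FileNotFoundError(
            f"stage extract: no mzML/MSP spectrum files under {mzml_dir}")
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "inputs": {str(p): _sha256(p) for p in
                   [*mzml_paths, Path(library_msp), Path(metadata_tsv),
                    *ontology_inputs]},
        "counts": {},
    }

    def stage(name: str):
        logger.info("stage %s", name)
        return out / name

    try:
        spectra, counts = extract_stage(config, mzml_paths, stage("extract"))
        manifest["counts"].update(counts)
    except Exception as exc:
        raise RuntimeError(f"stage extract failed: {exc}") from exc

    try:
        library = read_library_msp(library_msp, ontology)
        models = train_stage(config, library, ontology, stage("train"))
        manifest["counts"]["models_trainable"] = sum(m.trainable for m in models)
    except Exception as exc:
        raise RuntimeError(f"stage train failed: {exc}") from exc

    try:
        cdir = stage("classify")
        cdir.mkdir(parents=True, exist_ok=True)
        assignments = classify_all(models, spectra, alpha=config.alpha)
        classification.assignments_frame(assignments).to_csv(
            cdir / "assignments.tsv", sep="\t", index=False)
        unmatched = unmatched_ids(spectra, assignments)
        manifest["counts"]["classified_spectra"] = len(spectra) - len(unmatched)
        manifest["counts"]["unmatched"] = len(unmatched)
    except Exception as exc:
        raise RuntimeError(f"stage classify failed: {exc}") from exc

    try:
        ddir = stage("diversity")
        ddir.mkdir(parents=True, exist_ok=True)
        metadata = pd.read_csv(metadata_tsv, sep="\t", dtype=str)
        per_sample = chemodiversity.count_matrix(assignments, metadata,
                                                 group_by="sample",
                                                 class_ids=ontology.ids)
        per_sample.to_csv(ddir / "counts_sample.tsv", sep="\t")
        factor_matrices = {}
        for factor in ("species", "season"):
            if factor in metadata.columns:
                m = chemodiversity.count_matrix(assignments, metadata,
                                                group_by=factor,
                                                class_ids=ontology.ids)
                m.to_csv(ddir / f"counts_{factor}.tsv", sep="\t")
                factor_matrices[factor] = m
        chemodiversity.diversity_table(
            per_sample.loc[per_sample.sum(axis=1) > 0]).to_csv(
            ddir / "diversity_sample.tsv", sep="\t")
        sb, n_unmatched = chemodiversity.sunburst_counts(
            assignments, ontology, all_entities=[s.id for s in spectra])
        json.dump({"counts": sb.to_dict(), "unmatched": n_unmatched},
                  (ddir / "sunburst.json").open("w"))
    except Exception as exc:
        raise RuntimeError(f"stage diversity failed: {exc}") from exc

    try:
        tdir = stage("trees")
        tdir.mkdir(parents=True, exist_ok=True)
        tree_metrics = {}
        if "species" in factor_matrices:
            sp_counts = factor_matrices["species"]
            sp_counts = sp_counts.loc[sp_counts.sum(axis=1) > 0]
            if len(sp_counts) >= 2:
                dm = tree_comparison.bray_curtis(sp_counts)
                dm.to_frame().to_csv(tdir / "bray_curtis_species.tsv", sep="\t")
                chemo = tree_comparison.hclust(dm, method=config.linkage)
                tree_comparison.write_newick(chemo, tdir / "chemotaxonomy.nwk")
                if phylo_newick is not None:
                    phylo = tree_comparison.read_newick(phylo_newick)
                    tree_metrics["cophenetic_correlation"] = \
                        tree_comparison.cophenetic_correlation(chemo, phylo)
                    pd_dm = tree_comparison.cophenetic_dist(phylo)
                    r, p = tree_comparison.mantel(dm, pd_dm,
                                                  n_perm=config.n_perm,
                                                  seed=config.seed)
                    tree_metrics["mantel_r"] = r
                    tree_metrics["mantel_p"] = p
                    if len(sp_counts) >= 4:
                        tree_metrics["robinson_foulds_normalized"] = \
                            tree_comparison.robinson_foulds(chemo, phylo)
                        tree_metrics["rf_convention"] = (
                            "unrooted nontrivial bipartitions, symmetric "
                            "difference / total splits of both trees")
        json.dump(tree_metrics, (tdir / "tree_comparison.json").open("w"))
        manifest["tree_comparison"] = tree_metrics
    except Exception as exc:
        raise RuntimeError(f"stage trees failed: {exc}") from exc

    try:
        edir = stage("ecostats")
        edir.mkdir(parents=True, exist_ok=True)
        nonzero = per_sample.loc[per_sample.sum(axis=1) > 0]
        meta_idx = metadata.set_index("sample_id").loc[nonzero.index]
        if {"species", "season"}.issubset(meta_idx.columns) and len(nonzero) >= 4:
            dm = tree_comparison.bray_curtis(nonzero)
            fractions = eco_stats.varpart(dm, meta_idx["species"].tolist(),
                                          meta_idx["season"].tolist())
            fractions.to_csv(edir / "varpart.tsv", sep="\t")
            manifest["varpart_unadjusted"] = fractions.loc["unadjusted"].to_dict()
            if eco_tsv is not None:
                eco = pd.read_csv(eco_tsv, sep="\t").set_index("sample_id")
                eco = eco.loc[nonzero.index]
                ordination = eco_stats.dbrda(
                    dm, eco_stats.factor_design(meta_idx["species"].tolist()))
                fits = eco_stats.envfit(ordination, eco, n_perm=config.n_perm,
                                        seed=config.seed)
                eco_stats.envfit_frame(fits).to_csv(edir / "envfit.tsv",
                                                    sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage ecostats failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
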