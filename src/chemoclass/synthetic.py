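"""Synthetic reference libraries and study designs with known ground truth.

Spectra are simulated from *class motifs*: each compound class owns a set
of signature fragment bins that appear with high probability in member
spectra and with low probability elsewhere, on top of uniform noise peaks
whose intensities straddle the abundance threshold.  A *study design*
emulates the fully crossed sampling of the bryophyte field study —
9 species x 4 seasons x 3 replicates — with species- and season-dependent
compound-class frequencies evolved along a simulated species tree, so the
whole pipeline (extraction, classification, diversity, tree comparison,
variation partitioning) can be exercised against known truth without any
external data.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classification import ABUNDANCE_THRESHOLD, BIN_WIDTH
from .ontology import ChemOntClass, Ontology, ReferenceSpectrum
from .spectra_io import MASS_RANGE, RT_RANGE, FragmentSpectrum, Peak

#: Peak intensities are log-uniform over this range, so the abundance-100
#: threshold removes a realistic share of noise peaks.
INTENSITY_RANGE = (10.0, 1e5)
#: Signature peaks are guaranteed above the threshold.
SIGNATURE_INTENSITY_RANGE = (2.0 * ABUNDANCE_THRESHOLD, 1e5)


def toy_ontology() -> Ontology:
    """Three-level test hierarchy: root -> 3 superclasses -> 6 leaf classes."""
    classes = [ChemOntClass("9000000", "Root", None)]
    leaf = 0
    for s in range(3):
        sid = f"910000{s}"
        classes.append(ChemOntClass(sid, f"Superclass {s + 1}", "9000000"))
        for _ in range(2):
            leaf += 1
            classes.append(ChemOntClass(f"920000{leaf}", f"Leaf class {leaf}", sid))
    return Ontology(classes)


def toy_leaf_ids() -> list[str]:
    return [f"920000{i}" for i in range(1, 7)]


@dataclass(frozen=True)
class ClassMotif:
    """Class-specific fragmentation pattern.

    ``signature_bins`` index 0.01 Da fragment bins; a member spectrum
    contains each with probability ``p_in``, a non-member with ``p_bg``.
    ``noise_rate`` is the expected number of uniform noise peaks.
    """

    class_id: str
    signature_bins: frozenset[int]
    p_in: float = 0.9
    p_bg: float = 0.05
    noise_rate: float = 5.0

    def __post_init__(self) -> None:
        if not (0 <= self.p_bg <= self.p_in <= 1):
            raise ValueError("need 0 <= p_bg <= p_in <= 1")


def default_motifs(class_ids: Sequence[str] | None = None, n_bins: int = 8,
                   p_in: float = 0.9, p_bg: float = 0.05,
                   noise_rate: float = 5.0, seed: int = 0,
                   w: float = BIN_WIDTH) -> list[ClassMotif]:
    """Disjoint signature-bin motifs for the given classes (toy leaves by
    default), drawn reproducibly from the seed."""
    if class_ids is None:
        class_ids = toy_leaf_ids()
    rng = np.random.default_rng(seed)
    lo = int(MASS_RANGE[0] / w) + 1
    hi = int(MASS_RANGE[1] / w) - 1
    all_bins = rng.choice(np.arange(lo, hi), size=n_bins * len(class_ids),
                          replace=False)
    motifs = []
    for i, cid in enumerate(class_ids):
        bins = frozenset(int(b) for b in all_bins[i * n_bins:(i + 1) * n_bins])
        motifs.append(ClassMotif(class_id=cid, signature_bins=bins, p_in=p_in,
                                 p_bg=p_bg, noise_rate=noise_rate))
    return motifs


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size: int
                 ) -> np.ndarray:
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))


def _motif_peaks(motif: ClassMotif, others: Sequence[ClassMotif],
                 rng: np.random.Generator, member: bool,
                 w: float = BIN_WIDTH) -> tuple[Peak, ...]:
    """Draw a peak list: own signature bins at p_in (member) or p_bg, other
    classes' signature bins at their p_bg, plus Poisson noise peaks."""
    peaks: list[Peak] = []
    p_own = motif.p_in if member else motif.p_bg
    for b in sorted(motif.signature_bins):
        if rng.random() < p_own:
            mz = (b + 0.5) * w
            inten = _log_uniform(rng, *SIGNATURE_INTENSITY_RANGE, 1)[0]
            peaks.append(Peak(mz, float(inten)))
    for other in others:
        if other.class_id == motif.class_id:
            continue
        for b in sorted(other.signature_bins):
            if rng.random() < other.p_bg:
                mz = (b + 0.5) * w
                inten = _log_uniform(rng, *SIGNATURE_INTENSITY_RANGE, 1)[0]
                peaks.append(Peak(mz, float(inten)))
    n_noise = rng.poisson(motif.noise_rate)
    if n_noise:
        mzs = rng.uniform(MASS_RANGE[0], MASS_RANGE[1], size=n_noise)
        intens = _log_uniform(rng, *INTENSITY_RANGE, n_noise)
        peaks.extend(Peak(float(m), float(i)) for m, i in zip(mzs, intens))
    return tuple(peaks)


def make_library(motifs: Sequence[ClassMotif], ontology: Ontology,
                 n_per_class: int = 50, n_background: int = 100,
                 seed: int = 0, spectra_per_compound: int = 1,
                 w: float = BIN_WIDTH) -> list[ReferenceSpectrum]:
    """Simulate a labeled reference library.

    Per class, ``n_per_class`` member spectra are generated from its motif;
    ``n_background`` additional spectra carry no class label (pure
    background).  ``spectra_per_compound`` replicate spectra share one
    compound id (exercising compound-grouped cross-validation).  Lineages
    are closed over the ontology.
    """
    rng = np.random.default_rng(seed)
    out: list[ReferenceSpectrum] = []

    def precursor_rt() -> tuple[float, float]:
        return (float(rng.uniform(*MASS_RANGE)), float(rng.uniform(*RT_RANGE)))

    for motif in motifs:
        lineage = ontology.lineage(motif.class_id)
        n_compounds = max(1, n_per_class // spectra_per_compound)
        i = 0
        for comp in range(n_compounds):
            for _ in range(spectra_per_compound):
                if i >= n_per_class:
                    break
                prec, rt = precursor_rt()
                spec = FragmentSpectrum(
                    id=f"lib::{motif.class_id}_{i}",
                    sample_id="library",
                    precursor_mz=prec, rt=rt,
                    peaks=_motif_peaks(motif, motifs, rng, member=True, w=w),
                )
                out.append(ReferenceSpectrum(
                    spectrum=spec,
                    compound_id=f"{motif.class_id}_cmp{comp}",
                    class_lineage=lineage,
                ))
                i += 1
    ref_motif = motifs[0] if motifs else ClassMotif("none", frozenset())
    for i in range(n_background):
        prec, rt = precursor_rt()
        spec = FragmentSpectrum(
            id=f"lib::bg_{i}",
            sample_id="library",
            precursor_mz=prec, rt=rt,
            peaks=_motif_peaks(ref_motif, motifs, rng, member=False, w=w),
        )
        out.append(ReferenceSpectrum(spectrum=spec, compound_id=f"bg_cmp{i}",
                                     class_lineage=frozenset()))
    return out


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticDesign:
    """Fully crossed species x season sampling design.

    Effect sizes are standard deviations of log-rate shifts of per-class
    expected entity counts: a species effect of 1 and season effect of 0.1
    gives the 10:1 species-dominated structure of the field study.
    """

    n_species: int = 9
    n_seasons: int = 4
    replicates: int = 3
    species_effect: float = 1.0
    season_effect: float = 0.1
    base_rate: float = 5.0          # expected entities per (sample, class)
    noise_entities: float = 2.0     # expected unclassifiable entities/sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species_effect < 0 or self.season_effect < 0:
            raise ValueError("effect sizes must be >= 0")

    @property
    def species(self) -> list[str]:
        return [f"species_{i + 1:02d}" for i in range(self.n_species)]

    @property
    def seasons(self) -> list[str]:
        return ["spring", "summer", "autumn", "winter"][: self.n_seasons] + [
            f"season_{i}" for i in range(4, self.n_seasons)]


def _random_ultrametric_tree(labels: Sequence[str], rng: np.random.Generator
                             ) -> tuple[str, list[tuple[int, int, int]], int]:
    """Random ultrametric topology by successive pair merges.

    Returns (newick, merge list of (child_a, child_b, parent), root index)
    where indices < len(labels) are leaves.
    """
    n = len(labels)
    heights = np.sort(rng.uniform(0.1, 1.0, size=n - 1))
    active = list(range(n))
    height_of = {i: 0.0 for i in range(n)}
    newick_of = {i: labels[i] for i in range(n)}
    merges: list[tuple[int, int, int]] = []
    nxt = n
    for k in range(n - 1):
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        h = float(heights[k])
        newick_of[nxt] = (f"({newick_of[a]}:{h - height_of[a]:.6f},"
                          f"{newick_of[b]}:{h - height_of[b]:.6f})")
        height_of[nxt] = h
        merges.append((a, b, nxt))
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    root = active[0]
    return newick_of[root] + ";", merges, root


def _brownian_traits(n_leaves: int, merges: list[tuple[int, int, int]],
                     root: int, n_traits: int, rng: np.random.Generator
                     ) -> np.ndarray:
    """Evolve leaf trait vectors by Brownian motion along the merge tree."""
    parent = {}
    for a, b, p in merges:
        parent[a] = p
        parent[b] = p
    # depth = number of edges from root; per-edge variance 1/depth keeps
    # total leaf variance comparable across leaves
    traits = {root: np.zeros(n_traits)}
    children: dict[int, list[int]] = {}
    for a, b, p in merges:
        children[p] = [a, b]
    stack = [root]
    while stack:
        node = stack.pop()
        for ch in children.get(node, []):
            traits[ch] = traits[node] + rng.normal(0.0, 1.0, size=n_traits) * 0.7
            stack.append(ch)
    return np.vstack([traits[i] for i in range(n_leaves)])


@dataclass
class StudyData:
    """Everything a simulated field study produces, plus its ground truth."""

    spectra: dict[str, list[FragmentSpectrum]]   # sample_id -> unknown spectra
    metadata: pd.DataFrame                       # sample_id, species, season
    true_counts: pd.DataFrame                    # samples x class ids
    species_tree_newick: str
    true_entity_class: dict[str, str]            # spectrum id -> class id


def make_study(design: SyntheticDesign, motifs: Sequence[ClassMotif],
               seed: int | None = None, w: float = BIN_WIDTH,
               with_spectra: bool = True) -> StudyData:
    """Simulate per-sample unknown spectra under a crossed study design.

    Per-class expected entity counts are log-linear in a species trait
    (evolved along a random ultrametric species tree, scaled by
    ``species_effect``) and a season trait (i.i.d. normal, scaled by
    ``season_effect``); realized counts are Poisson.  Each entity becomes
    one fragment spectrum drawn from its class motif, inside the evaluated
    mass/RT windows by construction.  ``noise_entities`` unclassifiable
    spectra per sample carry no class signal.  With ``with_spectra=False``
    only the ground-truth count matrix, metadata and species tree are
    generated (cheap, for design-level simulations).
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    species = design.species
    seasons = design.seasons
    class_ids = [m.class_id for m in motifs]
    motif_of = {m.class_id: m for m in motifs}

    newick, merges, root = _random_ultrametric_tree(species, rng)
    sp_traits = _brownian_traits(len(species), merges, root, len(class_ids), rng)
    se_traits = rng.normal(0.0, 1.0, size=(len(seasons), len(class_ids)))

    rows = []
    spectra: dict[str, list[FragmentSpectrum]] = {}
    counts = {}
    entity_class: dict[str, str] = {}
    for si, sp in enumerate(species):
        for gi, se in enumerate(seasons):
            for rep in range(design.replicates):
                sample = f"{sp}_{se}_r{rep + 1}"
                rows.append({"sample_id": sample, "species": sp, "season": se})
                lam = design.base_rate * np.exp(
                    design.species_effect * sp_traits[si]
                    + design.season_effect * se_traits[gi])
                # keep expected totals bounded
                lam = np.minimum(lam, 50.0)
                n_entities = rng.poisson(lam)
                counts[sample] = n_entities
                sample_spectra: list[FragmentSpectrum] = []
                if not with_spectra:
                    spectra[sample] = sample_spectra
                    continue
                e = 0
                for ci, cid in enumerate(class_ids):
                    for _ in range(int(n_entities[ci])):
                        spec = FragmentSpectrum(
                            id=f"{sample}::e{e}",
                            sample_id=sample,
                            precursor_mz=float(rng.uniform(*MASS_RANGE)),
                            rt=float(rng.uniform(*RT_RANGE)),
                            peaks=_motif_peaks(motif_of[cid], motifs, rng,
                                               member=True, w=w),
                        )
                        entity_class[spec.id] = cid
                        sample_spectra.append(spec)
                        e += 1
                for _ in range(rng.poisson(design.noise_entities)):
                    ref = motifs[0]
                    spec = FragmentSpectrum(
                        id=f"{sample}::e{e}",
                        sample_id=sample,
                        precursor_mz=float(rng.uniform(*MASS_RANGE)),
                        rt=float(rng.uniform(*RT_RANGE)),
                        peaks=_motif_peaks(ref, motifs, rng, member=False, w=w),
                    )
                    sample_spectra.append(spec)
                    e += 1
                spectra[sample] = sample_spectra

    metadata = pd.DataFrame(rows)
    true_counts = pd.DataFrame.from_dict(counts, orient="index",
                                         columns=class_ids).sort_index()
    true_counts.index.name = "sample"
    return StudyData(spectra=spectra, metadata=metadata, true_counts=true_counts,
                     species_tree_newick=newick, true_entity_class=entity_class)
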