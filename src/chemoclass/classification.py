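"""Per-class compound classifiers on binned MS2 fragment peaks.

One binary classifier is trained per compound class from a
foreground/background split of the reference library.  A spectrum is
represented as the set of 0.01 Da fragment bins occupied by peaks above an
abundance threshold; the classifier is a naive-Bayes-style log-likelihood
ratio over those binary bins with Laplace smoothing.  Significance of a
score is assessed against the empirical score distribution of the
background spectra, and only assignments with p <= 0.05 are retained.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ontology import TrainingSplit
from .spectra_io import FragmentSpectrum, MergedSpectrum

logger = logging.getLogger("chemoclass")

#: Fragment-bin width in Da (matches the precursor merge tolerance).
BIN_WIDTH = 0.01
#: Fragment peaks must exceed this abundance to be featurized.
ABUNDANCE_THRESHOLD = 100.0
#: Retained assignments must satisfy p <= ALPHA.
ALPHA = 0.05
#: Laplace smoothing pseudo-count.
LAPLACE_ALPHA = 1.0


@dataclass(frozen=True)
class FragmentVector:
    """Occupied fragment bins of one spectrum (bin index = floor(mz / w))."""

    bins: frozenset[int]
    w: float = BIN_WIDTH
    threshold: float = ABUNDANCE_THRESHOLD

    def __len__(self) -> int:
        return len(self.bins)


def vectorize(spectrum: FragmentSpectrum | MergedSpectrum,
              w: float = BIN_WIDTH,
              threshold: float = ABUNDANCE_THRESHOLD) -> FragmentVector:
    """Bin the fragment peaks of a spectrum above the abundance threshold.

    Peaks with intensity strictly greater than ``threshold`` are kept and
    mapped to bin ``floor(mz / w)``; a spectrum with no qualifying peak
    yields an empty (valid) vector.
    """
    if w <= 0:
        raise ValueError(f"bin width must be positive, got {w}")
    spec = spectrum.representative if isinstance(spectrum, MergedSpectrum) else spectrum
    bins = frozenset(math.floor(p.mz / w) for p in spec.peaks if p.intensity > threshold)
    return FragmentVector(bins=bins, w=w, threshold=threshold)


@dataclass
class ClassifierModel:
    """Binned fragment statistics of one compound class.

    ``fg_counts``/``bg_counts`` are raw per-bin occurrence counts over the
    foreground/background training sets; smoothed rates and log-ratio
    weights are derived from them on demand.  ``background_scores`` holds
    the sorted scores of every background spectrum (the empirical null).
    """

    class_id: str
    w: float
    threshold: float
    n_foreground: int
    n_background: int
    alpha: float = LAPLACE_ALPHA
    fg_counts: dict[int, int] = field(default_factory=dict)
    bg_counts: dict[int, int] = field(default_factory=dict)
    background_scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    trainable: bool = True

    def fg_rate(self, b: int) -> float:
        """Smoothed foreground occurrence frequency of bin ``b``."""
        return (self.fg_counts.get(b, 0) + self.alpha) / (self.n_foreground + 2 * self.alpha)

    def bg_rate(self, b: int) -> float:
        """Smoothed background occurrence frequency of bin ``b``."""
        return (self.bg_counts.get(b, 0) + self.alpha) / (self.n_background + 2 * self.alpha)

    @property
    def base_weight(self) -> float:
        """log(fg_rate/bg_rate) of a bin never seen during training."""
        return (math.log(self.alpha / (self.n_foreground + 2 * self.alpha))
                - math.log(self.alpha / (self.n_background + 2 * self.alpha)))

    def bin_weights(self) -> tuple[dict[int, float], float]:
        """Sparse log-ratio weights: (delta per seen bin, unseen-bin base).

        The weight of bin ``b`` is ``base + delta.get(b, 0)``.
        """
        base = self.base_weight
        seen = set(self.fg_counts) | set(self.bg_counts)
        delta = {b: math.log(self.fg_rate(b)) - math.log(self.bg_rate(b)) - base
                 for b in seen}
        return delta, base


def train(split: TrainingSplit, w: float = BIN_WIDTH,
          threshold: float = ABUNDANCE_THRESHOLD,
          alpha: float = LAPLACE_ALPHA) -> ClassifierModel:
    """Train the log-likelihood-ratio model of one compound class.

    Per-bin rates are Laplace-smoothed occurrence frequencies
    ``(count + alpha) / (n + 2 alpha)`` in the foreground and background
    sets.  The empirical null distribution is populated by scoring every
    background spectrum *leave-one-out* (its own contribution removed from
    the background counts): in-sample scores would be anti-conservative,
    because a training background spectrum never receives the unseen-bin
    baseline weight that any fresh spectrum's novel bins receive, and the
    retained-assignment rate under a background-distributed null would far
    exceed the nominal alpha.  Untrainable splits yield a flagged model
    that never produces assignments.
    """
    model = ClassifierModel(
        class_id=split.class_id, w=w, threshold=threshold,
        n_foreground=len(split.foreground), n_background=len(split.background),
        alpha=alpha, trainable=split.trainable,
    )
    if not split.trainable:
        return model

    fg_vecs = [vectorize(r.spectrum, w, threshold) for r in split.foreground]
    bg_vecs = [vectorize(r.spectrum, w, threshold) for r in split.background]
    for v in fg_vecs:
        for b in v.bins:
            model.fg_counts[b] = model.fg_counts.get(b, 0) + 1
    for v in bg_vecs:
        for b in v.bins:
            model.bg_counts[b] = model.bg_counts.get(b, 0) + 1

    model.background_scores = np.sort(_loo_background_scores(model, bg_vecs))
    return model


def _loo_background_scores(model: ClassifierModel,
                           bg_vecs: Sequence[FragmentVector]) -> np.ndarray:
    """Score each background spectrum with itself removed from the counts.

    For an occupied bin b of spectrum i the background rate becomes
    ``(bg_count[b] - 1 + alpha) / (n_bg - 1 + 2 alpha)``; the foreground
    side is unchanged.  This makes the null scores exchangeable with the
    scores of background-distributed unseen spectra.
    """
    a = model.alpha
    nf = model.n_foreground
    nb = model.n_background
    out = np.empty(len(bg_vecs))
    for i, v in enumerate(bg_vecs):
        s = 0.0
        for b in v.bins:
            fg = (model.fg_counts.get(b, 0) + a) / (nf + 2 * a)
            bg = (model.bg_counts.get(b, 0) - 1 + a) / (nb - 1 + 2 * a)
            s += math.log(fg) - math.log(bg)
        out[i] = s
    return out


def score(model: ClassifierModel, v: FragmentVector) -> float:
    """Log-likelihood-ratio score of a fragment vector under one model.

    ``sum over occupied bins b of log(fg_rate[b] / bg_rate[b])``; an empty
    vector scores 0.
    """
    return float(score_many(model, [v])[0])


def score_many(model: ClassifierModel, vectors: Sequence[FragmentVector]) -> np.ndarray:
    """Vectorized scoring of many fragment vectors under one model."""
    if not model.trainable:
        raise ValueError(f"model for class {model.class_id} is untrainable")
    delta, base = model.bin_weights()
    return np.array([len(v.bins) * base + sum(delta.get(b, 0.0) for b in v.bins)
                     for v in vectors])


def empirical_p(model: ClassifierModel, s: float) -> float:
    """Right-tail empirical p-value of a score against the background null.

    ``p = (1 + #{background scores >= s}) / (N + 1)``; ties count toward the
    tail, and the add-one form keeps p in (0, 1].
    """
    return float(empirical_p_many(model, np.array([s]))[0])


def empirical_p_many(model: ClassifierModel, scores: np.ndarray) -> np.ndarray:
    bg = model.background_scores
    n = bg.size
    if n == 0:
        raise ValueError("model has no background score distribution")
    n_ge = n - np.searchsorted(bg, scores, side="left")
    return (1.0 + n_ge) / (n + 1.0)


@dataclass(frozen=True)
class ClassAssignment:
    spectrum_id: str
    class_id: str
    score: float
    p_value: float


def classify_all(models: Sequence[ClassifierModel],
                 spectra: Sequence[MergedSpectrum | FragmentSpectrum],
                 alpha: float = ALPHA) -> list[ClassAssignment]:
    """Score every spectrum under every trainable model; keep p <= alpha.

    The output is multi-label: one spectrum may carry assignments to several
    classes, including a class and its ancestor.  Spectra with no retained
    assignment are simply absent from the result ("not matched").
    """
    out: list[ClassAssignment] = []
    usable = [m for m in models if m.trainable]
    if not usable:
        return out
    ids = [s.id for s in spectra]
    # vectorization depends only on (w, threshold); cache across models
    vec_cache: dict[tuple[float, float], list[FragmentVector]] = {}
    for model in usable:
        key = (model.w, model.threshold)
        if key not in vec_cache:
            vec_cache[key] = [vectorize(s, *key) for s in spectra]
        vecs = vec_cache[key]
        scores = score_many(model, vecs)
        pvals = empirical_p_many(model, scores)
        keep = np.nonzero(pvals <= alpha)[0]
        out.extend(ClassAssignment(ids[i], model.class_id, float(scores[i]), float(pvals[i]))
                   for i in keep)
    return out


def unmatched_ids(spectra: Sequence[MergedSpectrum | FragmentSpectrum],
                  assignments: Iterable[ClassAssignment]) -> list[str]:
    """Ids of spectra that received no retained class assignment."""
    matched = {a.spectrum_id for a in assignments}
    return [s.id for s in spectra if s.id not in matched]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Serialize a model as versioned JSON with sparse per-bin counts."""
    bg = model.background_scores
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "class_id": model.class_id,
        "w": model.w,
        "threshold": model.threshold,
        "alpha": model.alpha,
        "n_foreground": model.n_foreground,
        "n_background": model.n_background,
        "trainable": model.trainable,
        "fg_bins": sorted(model.fg_counts),
        "fg_values": [model.fg_counts[b] for b in sorted(model.fg_counts)],
        "bg_bins": sorted(model.bg_counts),
        "bg_values": [model.bg_counts[b] for b in sorted(model.bg_counts)],
        "background_scores": [float(x) for x in bg],
        "background_score_quantiles": {
            str(q): float(np.quantile(bg, q)) for q in (0.5, 0.9, 0.95, 0.99)
        } if bg.size else {},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ClassifierModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format in {path}")
    return ClassifierModel(
        class_id=payload["class_id"], w=payload["w"],
        threshold=payload["threshold"], alpha=payload["alpha"],
        n_foreground=payload["n_foreground"], n_background=payload["n_background"],
        trainable=payload["trainable"],
        fg_counts=dict(zip(payload["fg_bins"], payload["fg_values"])),
        bg_counts=dict(zip(payload["bg_bins"], payload["bg_values"])),
        background_scores=np.asarray(payload["background_scores"], dtype=float),
    )


def assignments_frame(assignments: Iterable[ClassAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.spectrum_id, a.class_id, a.score, a.p_value) for a in assignments],
        columns=["spectrum_id", "class_id", "score", "p_value"],
    )
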