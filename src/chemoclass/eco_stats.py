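"""Constrained ordination and group-comparison statistics.

Distance-based redundancy analysis (dbRDA) regresses the principal
coordinates of a dissimilarity matrix on presence-absence coded study
factors; variation partitioning decomposes the explained community
variation into unique and shared fractions of two factor sets.  External
ecological variables are related to the ordination by least-squares vector
fitting with permutation significance (envfit), and individual factor
levels are compared by one-way ANOVA with Tukey HSD post-hoc letters.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .tree_comparison import DistanceMatrix

logger = logging.getLogger("chemoclass")


# ---------------------------------------------------------------------------
# dbRDA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    labels: tuple[str, ...]
    site_scores: np.ndarray          # samples x retained PCoA axes
    eigenvalues: np.ndarray          # positive eigenvalues, non-increasing
    total_inertia: float
    constrained_inertia: float
    constrained_fraction: float      # R^2 = constrained / total
    adjusted_fraction: float         # Ezekiel-adjusted R^2
    n_predictors: int                # rank of the predictor matrix (w/o intercept)


def _pcoa(dm: DistanceMatrix, correction: str | None = None
          ) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a dissimilarity matrix.

    Gower double-centering of -1/2 d^2; axes with non-positive eigenvalues
    are dropped (their magnitude is logged), or a Lingoes constant is added
    when ``correction='lingoes'``.
    """
    d = dm.d
    n = d.shape[0]
    if correction == "lingoes":
        neg = _pcoa_eigenvalues(d)
        c = -neg.min() if neg.min() < 0 else 0.0
        if c > 0:
            d = np.sqrt(d**2 + 2 * c)
            np.fill_diagonal(d, 0.0)
    A = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, abs(evals[0]))
    neg_mass = -evals[evals < -tol].sum()
    if neg_mass > 0:
        logger.info("dbRDA: dropped negative-eigenvalue axes "
                    "(total magnitude %.4g)", neg_mass)
    keep = evals > tol
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    return coords, evals[keep]


def _pcoa_eigenvalues(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return np.linalg.eigvalsh(J @ (-0.5 * d**2) @ J)


def factor_design(levels: Sequence[str]) -> pd.DataFrame:
    """Presence-absence (one-hot) coding of a categorical factor."""
    s = pd.Series(list(levels))
    return pd.get_dummies(s).astype(float)


def dbrda(dm: DistanceMatrix, predictors: pd.DataFrame | np.ndarray,
          correction: str | None = None) -> OrdinationResult:
    """Distance-based redundancy analysis.

    Site coordinates from PCoA of the dissimilarities are regressed on the
    (presence-absence coded) predictors; the constrained inertia is the sum
    of squares of the fitted coordinates and the explained fraction is
    constrained / total positive inertia.  Rank-deficient predictor
    matrices are handled by least squares (redundant columns carry no
    additional rank).  The Ezekiel-adjusted fraction
    ``1 - (1 - R^2)(n - 1)/(n - p - 1)`` is reported alongside.
    """
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(dm.labels)
    if X.shape[0] != n:
        raise ValueError("predictor rows must match distance-matrix labels")

    coords, evals = _pcoa(dm, correction=correction)
    total = float(evals.sum())

    Xc = X - X.mean(axis=0)
    rank = int(np.linalg.matrix_rank(Xc))
    if rank < Xc.shape[1]:
        # expected for one-hot factor coding (columns sum to the intercept);
        # least squares drops the redundancy, so only note it quietly
        logger.debug("dbRDA: predictor matrix is rank-deficient "
                     "(%d columns, rank %d)", Xc.shape[1], rank)
    # fitted values via least squares on centered coordinates
    Yc = coords - coords.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    constrained = float((fitted**2).sum())
    r2 = constrained / total if total > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - rank - 1) if n - rank - 1 > 0 else np.nan
    return OrdinationResult(
        labels=dm.labels, site_scores=coords, eigenvalues=evals,
        total_inertia=total, constrained_inertia=constrained,
        constrained_fraction=r2, adjusted_fraction=float(adj),
        n_predictors=rank,
    )


def varpart(dm: DistanceMatrix, factor_a: Sequence[str], factor_b: Sequence[str],
            correction: str | None = None) -> pd.DataFrame:
    """Two-factor variation partitioning from three dbRDA fits.

    Unique fractions are ``R2(A+B) - R2(B)`` and ``R2(A+B) - R2(A)``, the
    shared fraction ``R2(A) + R2(B) - R2(A+B)``, the residual the
    complement; the four fractions sum to 1 exactly.  Both unadjusted and
    Ezekiel-adjusted fractions are reported.
    """
    Xa = factor_design(factor_a).to_numpy()
    Xb = factor_design(factor_b).to_numpy()
    Xab = np.hstack([Xa, Xb])

    fit_a = dbrda(dm, Xa, correction=correction)
    fit_b = dbrda(dm, Xb, correction=correction)
    fit_ab = dbrda(dm, Xab, correction=correction)

    rows = {}
    for kind, (ra, rb, rab) in {
        "unadjusted": (fit_a.constrained_fraction, fit_b.constrained_fraction,
                       fit_ab.constrained_fraction),
        "adjusted": (fit_a.adjusted_fraction, fit_b.adjusted_fraction,
                     fit_ab.adjusted_fraction),
    }.items():
        unique_a = rab - rb
        unique_b = rab - ra
        shared = ra + rb - rab
        rows[kind] = {"unique_a": unique_a, "unique_b": unique_b,
                      "shared": shared, "residual": 1.0 - rab, "full": rab}
    shared_warn = rows["unadjusted"]["shared"]
    if shared_warn > max(rows["unadjusted"]["unique_a"], rows["unadjusted"]["unique_b"]):
        logger.warning("varpart: shared fraction (%.3f) dominates the unique "
                       "fractions; the factors may be confounded", shared_warn)
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# envfit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvfitResult:
    variable: str
    direction: tuple[float, ...]  # unit vector in ordination space
    r2: float
    p: float
    constant: bool = False


def envfit(ordination: OrdinationResult, variables: pd.DataFrame,
           n_axes: int = 2, n_perm: int = 999, seed: int = 0
           ) -> list[EnvfitResult]:
    """Least-squares fit of external variables onto ordination axes.

    Each variable is regressed on the first ``n_axes`` site-score axes;
    r^2 is the squared multiple correlation, the direction the normalized
    coefficient vector, and the p-value the add-one permutation tail of
    r^2 under row shuffling of the variable.  Constant variables are
    flagged with r^2 = 0 and p = 1.
    """
    if ordination.site_scores.shape[1] < n_axes:
        raise ValueError(f"ordination has fewer than {n_axes} axes")
    Y = ordination.site_scores[:, :n_axes]
    Yc = Y - Y.mean(axis=0)
    rng = np.random.default_rng(seed)
    n = Y.shape[0]

    out = []
    for name in variables.columns:
        v = variables[name].to_numpy(dtype=float)
        if v.shape[0] != n:
            raise ValueError(f"variable {name!r} has {v.shape[0]} values for "
                             f"{n} samples")
        if np.ptp(v) == 0:
            out.append(EnvfitResult(name, (0.0,) * n_axes, 0.0, 1.0, constant=True))
            continue
        r2_obs, direction = _fit_r2(Yc, v, return_direction=True)
        count = 0
        for _ in range(n_perm):
            if _fit_r2(Yc, v[rng.permutation(n)]) >= r2_obs - 1e-12:
                count += 1
        p = (1 + count) / (n_perm + 1)
        out.append(EnvfitResult(name, tuple(direction), float(r2_obs), float(p)))
    return out


def _fit_r2(Yc: np.ndarray, v: np.ndarray, return_direction: bool = False):
    vc = v - v.mean()
    sst = float(vc @ vc)
    beta, *_ = np.linalg.lstsq(Yc, vc, rcond=None)
    fitted = Yc @ beta
    r2 = float(fitted @ fitted) / sst if sst > 0 else 0.0
    if not return_direction:
        return r2
    norm = np.linalg.norm(beta)
    direction = beta / norm if norm > 0 else beta
    return r2, direction


def envfit_frame(results: Sequence[EnvfitResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variable": r.variable, "r2": r.r2, "p": r.p,
        **{f"axis{i+1}": c for i, c in enumerate(r.direction)},
    } for r in results])


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD compact letter display
# ---------------------------------------------------------------------------

@dataclass
class TukeyCLD:
    groups: tuple[str, ...]
    means: dict[str, float]
    p_adjusted: pd.DataFrame  # symmetric matrix of Tukey-adjusted p-values
    letters: dict[str, str]   # letter set per group
    f_statistic: float
    anova_p: float


def anova_tukey_cld(values: Mapping[str, Sequence[float]], alpha: float = 0.05
                    ) -> TukeyCLD:
    """One-way ANOVA with all-pairs Tukey HSD and compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``
    (Tukey-adjusted).  Letters are produced by the insert-and-absorb
    algorithm over the pairwise significance matrix.
    """
    groups = tuple(sorted(values))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(values[g], dtype=float) for g in groups}
    for g, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} needs at least two observations")

    f_stat, anova_p = _stats.f_oneway(*(arrays[g] for g in groups))
    if not np.isfinite(f_stat):
        # zero within-group variance everywhere with equal means
        f_stat, anova_p = 0.0, 1.0

    flat = np.concatenate([arrays[g] for g in groups])
    labels = np.concatenate([[g] * arrays[g].size for g in groups])
    if np.ptp(flat) == 0:
        padj = pd.DataFrame(1.0, index=groups, columns=groups)
    else:
        tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
        padj = pd.DataFrame(1.0, index=groups, columns=groups)
        res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, row in res.iterrows():
            g1, g2, p = str(row["group1"]), str(row["group2"]), float(row["p-adj"])
            padj.loc[g1, g2] = padj.loc[g2, g1] = p

    letters = compact_letter_display(padj, alpha=alpha)
    means = {g: float(arrays[g].mean()) for g in groups}
    return TukeyCLD(groups=groups, means=means, p_adjusted=padj,
                    letters=letters, f_statistic=float(f_stat),
                    anova_p=float(anova_p))


def compact_letter_display(p_adjusted: pd.DataFrame, alpha: float = 0.05
                           ) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their adjusted p-value is >= alpha
    (i.e. they are not significantly different).
    """
    groups = list(p_adjusted.index)
    # letter groups: maximal sets of mutually non-different groups
    letter_sets: list[set[str]] = [set(groups)]
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            if p_adjusted.loc[g1, g2] < alpha:
                new_sets: list[set[str]] = []
                for s in letter_sets:
                    if g1 in s and g2 in s:
                        s1, s2 = s - {g2}, s - {g1}
                        new_sets.extend([s1, s2])
                    else:
                        new_sets.append(s)
                # absorb: drop sets contained in another
                letter_sets = [s for s in new_sets
                               if not any(s < t for t in new_sets)]
                # deduplicate
                seen: list[set[str]] = []
                for s in letter_sets:
                    if s not in seen:
                        seen.append(s)
                letter_sets = seen

    # stable, readable letter order: by the first member's position
    letter_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = string.ascii_lowercase
    out: dict[str, list[str]] = {g: [] for g in groups}
    for k, s in enumerate(letter_sets):
        letter = alphabet[k % 26] * (k // 26 + 1)
        for g in s:
            out[g].append(letter)
    return {g: "".join(sorted(v)) for g, v in out.items()}


def cld_frame(result: TukeyCLD) -> pd.DataFrame:
    return pd.DataFrame({
        "group": result.groups,
        "mean": [result.means[g] for g in result.groups],
        "letters": [result.letters[g] for g in result.groups],
    })
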