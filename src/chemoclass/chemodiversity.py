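"""Chemodiversity statistics over compound-class assignments.

Retained class assignments are tallied into a samples (or factor-level)
x classes matrix of distinct chemical-entity counts, from which richness,
factor-level uniqueness, Shannon diversity H' (nats), Pielou evenness J,
and ontology-aggregated ("sunburst") counts are derived.  A chemical
entity is one merged, filtered MS2 spectrum, treated as a proxy for one
compound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _entropy

from .classification import ClassAssignment
from .ontology import Ontology

logger = logging.getLogger("chemoclass")


def count_matrix(assignments: Iterable[ClassAssignment],
                 metadata: pd.DataFrame, group_by: str = "sample",
                 class_ids: Sequence[str] | None = None,
                 entity_of: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Tally distinct chemical entities per (group, compound class).

    ``metadata`` is indexed by (or carries a column) ``sample_id`` plus one
    column per study factor; ``group_by`` is ``"sample"`` or a factor
    column (e.g. ``"species"``, ``"season"``).  An entity is counted once
    per (group, class) however many spectra or samples support it.
    ``entity_of`` maps spectrum id to a cross-sample entity id; identity by
    default.  Samples referenced by assignments but absent from the
    metadata are a hard error.
    """
    meta = metadata.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    assignments = list(assignments)
    entity_of = entity_of or {}

    def sample_of(spectrum_id: str) -> str:
        return spectrum_id.split("::", 1)[0]

    unknown = sorted({sample_of(a.spectrum_id) for a in assignments}
                     - set(meta.index))
    if unknown:
        raise KeyError(f"assignments reference samples missing from metadata: {unknown}")

    if group_by == "sample":
        group_of = {s: s for s in meta.index}
    else:
        if group_by not in meta.columns:
            raise KeyError(f"metadata has no factor column {group_by!r}")
        group_of = meta[group_by].astype(str).to_dict()

    seen: set[tuple[str, str, str]] = set()
    tallies: dict[tuple[str, str], int] = {}
    for a in assignments:
        sample = sample_of(a.spectrum_id)
        entity = entity_of.get(a.spectrum_id, a.spectrum_id)
        key = (group_of[sample], a.class_id, entity)
        if key in seen:
            continue
        seen.add(key)
        tallies[key[:2]] = tallies.get(key[:2], 0) + 1

    groups = sorted(set(group_of.values()))
    if class_ids is None:
        class_ids = sorted({a.class_id for a in assignments})
    mat = pd.DataFrame(0, index=groups, columns=list(class_ids), dtype=int)
    for (g, c), n in tallies.items():
        if c in mat.columns:
            mat.loc[g, c] = n
    mat.index.name = group_by
    return mat


def unique_entities(presence: pd.DataFrame) -> pd.Series:
    """Entities exclusive to one factor level.

    ``presence`` is an entities x levels table (nonzero = present at that
    level).  Returns, per level, the number of entities present there and
    nowhere else.
    """
    if presence.shape[1] < 2:
        raise ValueError("uniqueness needs at least two factor levels")
    present = presence.to_numpy() != 0
    exclusive = present & (present.sum(axis=1, keepdims=True) == 1)
    return pd.Series(exclusive.sum(axis=0), index=presence.columns, name="n_unique")


@dataclass(frozen=True)
class DiversityIndices:
    richness: int
    n_unique: int | None
    shannon_h: float
    pielou_j: float | None  # undefined (None) for richness <= 1


def diversity(abundances: Sequence[float], n_unique: int | None = None
              ) -> DiversityIndices:
    """Shannon H' (nats) and Pielou evenness J of an abundance vector.

    ``H' = -sum p_i ln p_i`` over the positive entries' relative
    abundances; ``J = H' / ln S`` with S the number of positive entries,
    undefined for S <= 1.
    """
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("diversity undefined for an all-zero abundance vector")
    h = float(_entropy(x))  # normalizes to proportions; natural log
    s = int(x.size)
    j = h / np.log(s) if s > 1 else None
    return DiversityIndices(richness=s, n_unique=n_unique, shannon_h=h,
                            pielou_j=None if j is None else float(j))


def diversity_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise diversity indices of a count matrix."""
    rows = []
    for g, row in matrix.iterrows():
        d = diversity(row.to_numpy())
        rows.append({"group": g, "richness": d.richness,
                     "shannon_h": d.shannon_h, "pielou_j": d.pielou_j})
    cols = ["group", "richness", "shannon_h", "pielou_j"]
    return pd.DataFrame(rows, columns=cols).set_index("group")


def sunburst_counts(assignments: Iterable[ClassAssignment], ontology: Ontology,
                    all_entities: Sequence[str] | None = None,
                    entity_of: Mapping[str, str] | None = None
                    ) -> tuple[pd.Series, int]:
    """Entity counts per class aggregated over all ancestor classes.

    Each entity contributes one count to every class in the union of the
    lineages of its retained assignments (deduplicated), so parents
    accumulate their descendants' entities and the root count equals the
    number of entities with at least one assignment.  Returns the per-class
    counts and the number of unmatched entities (those in ``all_entities``
    with no assignment).
    """
    entity_of = entity_of or {}
    per_entity: dict[str, set[str]] = {}
    for a in assignments:
        if a.class_id not in ontology:
            raise KeyError(f"assignment to unknown class id {a.class_id}")
        entity = entity_of.get(a.spectrum_id, a.spectrum_id)
        per_entity.setdefault(entity, set()).update(ontology.lineage(a.class_id))

    counts = pd.Series(0, index=ontology.ids, dtype=int)
    for lineage in per_entity.values():
        for c in lineage:
            counts[c] += 1

    if all_entities is None:
        n_unmatched = 0
    else:
        entities = {entity_of.get(e, e) for e in all_entities}
        n_unmatched = len(entities - set(per_entity))
    return counts, n_unmatched


def sunburst_json(counts: pd.Series, ontology: Ontology) -> list[dict]:
    """Nested class/count/children structure for sunburst rendering."""
    def node(cid: str) -> dict:
        return {
            "chemont_id": cid,
            "name": ontology.name(cid),
            "count": int(counts.get(cid, 0)),
            "children": [node(ch) for ch in ontology.children(cid)
                         if counts.get(ch, 0) > 0],
        }
    return [node(r) for r in ontology.roots()]


def log_scaled(matrix: pd.DataFrame) -> pd.DataFrame:
    """log(1 + x) transform used for heatmap export (keeps zeros finite)."""
    return np.log1p(matrix)
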