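"""ChemOnt class hierarchy and labeled reference spectral libraries.

The ontology is a rooted tree (or forest) of compound classes identified by
7-digit ChemOnt ids.  Reference spectra carry a *lineage*: the compound's
most specific class(es) plus all their ancestors, so that a flavonoid
glycoside is also a member of Flavonoids and every class above it.  From a
library, per-class foreground/background training splits are derived.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .spectra_io import FragmentSpectrum, read_msp

logger = logging.getLogger("chemoclass")

#: Classes with fewer foreground spectra than this are reported but not
#: trained: an empirical p-value and a PR curve are meaningless below it.
MIN_FOREGROUND = 10


@dataclass(frozen=True)
class ChemOntClass:
    chemont_id: str
    name: str
    parent_id: str | None  # None for a root


class Ontology:
    """Queryable compound-class hierarchy with acyclic parent links."""

    def __init__(self, classes: Iterable[ChemOntClass]) -> None:
        self._classes: dict[str, ChemOntClass] = {}
        for c in classes:
            if c.chemont_id in self._classes:
                raise ValueError(f"duplicate ChemOnt id {c.chemont_id}")
            self._classes[c.chemont_id] = c
        for c in self._classes.values():
            if c.parent_id is not None and c.parent_id not in self._classes:
                raise ValueError(
                    f"class {c.chemont_id} ({c.name}) has dangling parent id "
                    f"{c.parent_id}")
        self._check_acyclic()
        self._children: dict[str, list[str]] = {cid: [] for cid in self._classes}
        for c in self._classes.values():
            if c.parent_id is not None:
                self._children[c.parent_id].append(c.chemont_id)

    def _check_acyclic(self) -> None:
        for start in self._classes:
            seen: list[str] = []
            cur: str | None = start
            while cur is not None:
                if cur in seen:
                    cycle = seen[seen.index(cur):] + [cur]
                    raise ValueError(f"cycle in ontology parent links: {' -> '.join(cycle)}")
                seen.append(cur)
                cur = self._classes[cur].parent_id

    def __contains__(self, chemont_id: str) -> bool:
        return chemont_id in self._classes

    def __len__(self) -> int:
        return len(self._classes)

    @property
    def ids(self) -> list[str]:
        return sorted(self._classes)

    def name(self, chemont_id: str) -> str:
        return self._classes[chemont_id].name

    def parent(self, chemont_id: str) -> str | None:
        return self._classes[chemont_id].parent_id

    def roots(self) -> list[str]:
        return sorted(c.chemont_id for c in self._classes.values() if c.parent_id is None)

    def children(self, chemont_id: str) -> list[str]:
        return sorted(self._children[chemont_id])

    def ancestors(self, chemont_id: str) -> set[str]:
        """All strict ancestors of a class, up to and including the root."""
        out: set[str] = set()
        cur = self._classes[chemont_id].parent_id
        while cur is not None:
            out.add(cur)
            cur = self._classes[cur].parent_id
        return out

    def descendants(self, chemont_id: str) -> set[str]:
        out: set[str] = set()
        stack = list(self._children[chemont_id])
        while stack:
            c = stack.pop()
            out.add(c)
            stack.extend(self._children[c])
        return out

    def is_a(self, chemont_id: str, ancestor_id: str) -> bool:
        """True when ``chemont_id`` equals or descends from ``ancestor_id``."""
        return chemont_id == ancestor_id or ancestor_id in self.ancestors(chemont_id)

    def lineage(self, chemont_id: str) -> frozenset[str]:
        """The class itself plus all its ancestors (closed under parent)."""
        return frozenset({chemont_id} | self.ancestors(chemont_id))


def load_ontology(source: str | Path | pd.DataFrame) -> Ontology:
    """Load an ontology from a TSV (chemont_id, name, parent_id) or DataFrame.

    An empty/missing parent_id marks a root.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"chemont_id", "name", "parent_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"ontology table needs columns {sorted(required)}")
    classes = []
    for row in df.itertuples(index=False):
        parent = getattr(row, "parent_id")
        if parent is None or (isinstance(parent, float)) or str(parent).strip() == "" or str(parent) == "nan":
            parent = None
        else:
            parent = str(parent).strip()
        classes.append(ChemOntClass(str(row.chemont_id).strip(), str(row.name).strip(), parent))
    return Ontology(classes)


def study_ontology() -> Ontology:
    """The packaged hierarchy of the 35 bryophyte-study compound classes."""
    ref = importlib.resources.files("chemoclass.data") / "chemont_classes.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_ontology(path)


# ---------------------------------------------------------------------------
# Reference library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceSpectrum:
    """A library spectrum of a known compound with its ChemOnt lineage."""

    spectrum: FragmentSpectrum
    compound_id: str
    class_lineage: frozenset[str]

    @property
    def id(self) -> str:
        return self.spectrum.id


def annotate_library(spectra: Sequence[FragmentSpectrum],
                     compound_ids: Mapping[str, str],
                     classes: Mapping[str, Iterable[str]],
                     ontology: Ontology) -> list[ReferenceSpectrum]:
    """Attach compound ids and lineage-closed class sets to spectra.

    ``classes`` maps spectrum id to the compound's most specific class id(s);
    the stored lineage is their closure under the ontology's parent links.
    """
    out = []
    for s in spectra:
        leaf_classes = classes.get(s.id, ())
        lineage: set[str] = set()
        for c in leaf_classes:
            if c not in ontology:
                raise KeyError(f"spectrum {s.id}: unknown class id {c}")
            lineage |= ontology.lineage(c)
        out.append(ReferenceSpectrum(
            spectrum=s,
            compound_id=compound_ids.get(s.id, s.id),
            class_lineage=frozenset(lineage),
        ))
    return out


def read_library_msp(path: str | Path, ontology: Ontology) -> list[ReferenceSpectrum]:
    """Read a reference library MSP whose Comment fields carry annotations.

    The expected Comment syntax is ``InChIKey=<key>; ChemOnt=<id;id;...>``
    where the listed ids are the compound's most specific classes.
    """
    spectra, comments = read_msp(path)
    compound_ids: dict[str, str] = {}
    classes: dict[str, list[str]] = {}
    for sid, comment in comments.items():
        for fieldstr in comment.split(";"):
            fieldstr = fieldstr.strip()
            if fieldstr.startswith("InChIKey="):
                compound_ids[sid] = fieldstr.split("=", 1)[1].strip()
        if "ChemOnt=" in comment:
            tail = comment.split("ChemOnt=", 1)[1]
            tokens = [tok.strip() for tok in tail.replace(",", ";").split(";")]
            classes[sid] = [c for c in tokens if c and c.isdigit()]
    return annotate_library(spectra, compound_ids, classes, ontology)


def write_library_msp(library: Sequence[ReferenceSpectrum], path: str | Path,
                      ontology: Ontology | None = None) -> None:
    """Write a reference library with annotation Comments (round-trips)."""
    from .spectra_io import write_msp

    comments = {}
    for ref in library:
        # persist the most specific classes: lineage members with no child
        # in the lineage
        lineage = ref.class_lineage
        if ontology is not None:
            leaves = sorted(c for c in lineage
                            if not (set(ontology.children(c)) & lineage))
        else:
            leaves = sorted(lineage)
        comments[ref.id] = f"InChIKey={ref.compound_id}; ChemOnt={';'.join(leaves)}"
    write_msp([r.spectrum for r in library], path, comments=comments)


# ---------------------------------------------------------------------------
# Foreground / background splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingSplit:
    """Per-class partition of a library into member and non-member spectra."""

    class_id: str
    foreground: tuple[ReferenceSpectrum, ...]
    background: tuple[ReferenceSpectrum, ...]

    @property
    def trainable(self) -> bool:
        return len(self.foreground) >= MIN_FOREGROUND and len(self.background) >= 1


def build_split(library: Sequence[ReferenceSpectrum], class_id: str,
                ontology: Ontology | None = None) -> TrainingSplit:
    """Partition a library into foreground/background for one class.

    Membership is by lineage: any spectrum whose class lineage contains
    ``class_id`` is foreground, all remaining spectra are background.
    A split with fewer than ``MIN_FOREGROUND`` member spectra (or an empty
    background, e.g. the root class) is flagged untrainable rather than
    raising.
    """
    if ontology is not None and class_id not in ontology:
        raise KeyError(f"unknown class id {class_id}")
    fg = tuple(r for r in library if class_id in r.class_lineage)
    bg = tuple(r for r in library if class_id not in r.class_lineage)
    split = TrainingSplit(class_id=class_id, foreground=fg, background=bg)
    if not split.trainable:
        logger.info("class %s untrainable: %d foreground / %d background",
                    class_id, len(fg), len(bg))
    return split


def split_summary(splits: Iterable[TrainingSplit]) -> pd.DataFrame:
    """Summary counts per class (for JSON/TSV export)."""
    rows = [{"class_id": s.class_id,
             "n_foreground": len(s.foreground),
             "n_background": len(s.background),
             "trainable": s.trainable} for s in splits]
    return pd.DataFrame(rows)
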