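"""Reading, merging and filtering of DDA MS2 fragment spectra.

MS2 scans are extracted from mzML (one :class:`FragmentSpectrum` per scan),
replicate fragmentation events of the same precursor are merged within
mass/retention-time tolerances, and the merged spectra are restricted to the
evaluated precursor-mass and retention-time windows.  Spectra are exchanged
on disk in the NIST MSP text dialect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("chemoclass")

# Defaults for merging and evaluation windows (Da / seconds).
MZ_TOL = 0.01
RT_TOL = 5.0
MASS_RANGE = (50.0, 1000.0)
RT_RANGE = (10.0, 1020.0)

#: m/z values are persisted with 4 decimals, intensities with 1.
MZ_DECIMALS = 4
INTENSITY_DECIMALS = 1


@dataclass(frozen=True)
class Peak:
    """A single fragment peak: m/z in Da, intensity in arbitrary counts."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class FragmentSpectrum:
    """One MS2 scan: precursor m/z (Da), retention time (s), peak list.

    Peaks are kept sorted strictly ascending in m/z; duplicate m/z values
    are collapsed to the maximum intensity at construction.
    """

    id: str
    sample_id: str
    precursor_mz: float
    rt: float
    peaks: tuple[Peak, ...] = ()
    charge: int | None = None
    collision_energy: float | None = None

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValueError(f"precursor m/z must be positive, got {self.precursor_mz}")
        if self.rt < 0:
            raise ValueError(f"retention time must be >= 0, got {self.rt}")
        if self.charge is not None and self.charge < 1:
            raise ValueError(f"charge must be >= 1 or None, got {self.charge}")
        object.__setattr__(self, "peaks", _normalize_peaks(self.peaks))

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)


@dataclass(frozen=True)
class MergedSpectrum:
    """Consensus of one or more replicate fragmentation events."""

    representative: FragmentSpectrum
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.member_ids) < 1:
            raise ValueError("a merged spectrum needs at least one member")

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def id(self) -> str:
        return self.representative.id

    @property
    def sample_id(self) -> str:
        return self.representative.sample_id

    @property
    def precursor_mz(self) -> float:
        return self.representative.precursor_mz

    @property
    def rt(self) -> float:
        return self.representative.rt


def _normalize_peaks(peaks: Iterable[Peak]) -> tuple[Peak, ...]:
    """Sort ascending in m/z; collapse exact duplicates to the max intensity."""
    by_mz: dict[float, float] = {}
    for p in peaks:
        if p.mz in by_mz:
            by_mz[p.mz] = max(by_mz[p.mz], p.intensity)
        else:
            by_mz[p.mz] = p.intensity
    return tuple(Peak(mz, by_mz[mz]) for mz in sorted(by_mz))


# ---------------------------------------------------------------------------
# mzML input
# ---------------------------------------------------------------------------

_NS = "{http://psi.hupo.org/ms/mzml}"

# PSI-MS controlled-vocabulary accessions used while parsing
_CV_MS_LEVEL = "MS:1000511"
_CV_SCAN_START = "MS:1000016"
_CV_SELECTED_MZ = "MS:1000744"
_CV_CHARGE = "MS:1000041"
_CV_COLLISION_E = "MS:1000045"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"


def read_mzml(path: str | Path, sample_id: str | None = None) -> list[FragmentSpectrum]:
    """Extract all MS level-2 scans from an mzML file.

    MS1 scans are ignored.  Retention times are normalized to seconds
    regardless of the unit declared in the file.  MS2 scans without a
    precursor record are skipped with a warning; an unreadable file raises.
    Binary peak arrays may be 32- or 64-bit floats, zlib-compressed or not.

    Parameters
    ----------
    path:
        mzML file to read.
    sample_id:
        Sample identifier attached to every spectrum; defaults to the
        file stem.
    """
    from lxml import etree

    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    if not path.exists():
        raise FileNotFoundError(f"mzML file not found: {path}")

    out: list[FragmentSpectrum] = []
    try:
        context = etree.iterparse(str(path), events=("end",),
                                  tag=f"{_NS}spectrum")
        for _, elem in context:
            scan = _parse_spectrum_element(elem)
            elem.clear()
            if scan is None or scan["ms_level"] != 2:
                continue
            if scan["precursor_mz"] is None:
                logger.warning("MS2 scan %s in %s lacks a precursor m/z; skipped",
                               scan["id"], path.name)
                continue
            peaks = tuple(Peak(float(m), float(i))
                          for m, i in zip(scan["mz"], scan["intensity"]) if m > 0)
            out.append(FragmentSpectrum(
                id=f"{sample_id}::{scan['id']}",
                sample_id=sample_id,
                precursor_mz=scan["precursor_mz"],
                rt=scan["rt"],
                peaks=peaks,
                charge=scan["charge"],
                collision_energy=scan["collision_energy"],
            ))
    except etree.XMLSyntaxError as exc:
        raise IOError(f"cannot parse mzML file {path}: {exc}") from exc
    return out


def _cv(elem, accession: str):
    """First cvParam with the given accession below ``elem`` (or None)."""
    for cv in elem.iter(f"{_NS}cvParam"):
        if cv.get("accession") == accession:
            return cv
    return None


def _parse_spectrum_element(elem) -> dict | None:
    level_cv = _cv(elem, _CV_MS_LEVEL)
    ms_level = int(level_cv.get("value")) if level_cv is not None else None

    rt = 0.0
    for scan in elem.iter(f"{_NS}scan"):
        t_cv = _cv(scan, _CV_SCAN_START)
        if t_cv is not None:
            rt = float(t_cv.get("value"))
            unit = (t_cv.get("unitName") or "").lower()
            if "minute" in unit:
                rt *= 60.0
        break

    precursor_mz = charge = collision_energy = None
    for prec in elem.iter(f"{_NS}precursor"):
        for ion in prec.iter(f"{_NS}selectedIon"):
            mz_cv = _cv(ion, _CV_SELECTED_MZ)
            if mz_cv is not None:
                precursor_mz = float(mz_cv.get("value"))
            ch_cv = _cv(ion, _CV_CHARGE)
            if ch_cv is not None:
                charge = int(ch_cv.get("value"))
            break
        for act in prec.iter(f"{_NS}activation"):
            ce_cv = _cv(act, _CV_COLLISION_E)
            if ce_cv is not None:
                collision_energy = float(ce_cv.get("value"))
            break
        break

    mz = intensity = np.empty(0)
    for arr in elem.iter(f"{_NS}binaryDataArray"):
        values = _decode_binary_array(arr)
        if values is None:
            continue
        if _cv(arr, _CV_MZ_ARRAY) is not None:
            mz = values
        elif _cv(arr, _CV_INT_ARRAY) is not None:
            intensity = values

    return {
        "id": elem.get("id", "scan=?"),
        "ms_level": ms_level,
        "rt": rt,
        "precursor_mz": precursor_mz,
        "charge": charge,
        "collision_energy": collision_energy,
        "mz": mz,
        "intensity": intensity,
    }


def _decode_binary_array(arr) -> np.ndarray | None:
    import base64
    import zlib

    binary = arr.find(f"{_NS}binary")
    if binary is None or binary.text is None:
        return np.empty(0)
    raw = base64.b64decode(binary.text.strip())
    if _cv(arr, _CV_ZLIB) is not None:
        raw = zlib.decompress(raw)
    dtype = np.float32 if _cv(arr, _CV_F32) is not None else np.float64
    return np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<")).astype(float)


# ---------------------------------------------------------------------------
# NIST MSP dialect
# ---------------------------------------------------------------------------

def write_msp(spectra: Sequence[FragmentSpectrum | MergedSpectrum], path: str | Path,
              comments: dict[str, str] | None = None) -> None:
    """Write spectra as NIST MSP entries.

    Each entry carries ``Name``, ``PrecursorMZ``, ``RetentionTime``,
    optional ``Comment`` and ``Num Peaks`` headers followed by one
    ``mz intensity`` pair per line.  m/z values are written with 4 decimals
    and round-trip losslessly at that precision.

    ``comments`` maps spectrum id to a free-text Comment line (used e.g.
    to carry compound and class annotations of reference libraries).
    """
    path = Path(path)
    comments = comments or {}
    with path.open("w") as fh:
        for entry in spectra:
            spec = entry.representative if isinstance(entry, MergedSpectrum) else entry
            fh.write(f"Name: {spec.id}\n")
            fh.write(f"PrecursorMZ: {spec.precursor_mz:.{MZ_DECIMALS}f}\n")
            fh.write(f"RetentionTime: {spec.rt:.3f}\n")
            if spec.charge is not None:
                fh.write(f"Charge: {spec.charge}\n")
            if spec.collision_energy is not None:
                fh.write(f"CollisionEnergy: {spec.collision_energy:g}\n")
            if isinstance(entry, MergedSpectrum):
                fh.write(f"NumMembers: {entry.n_members}\n")
                fh.write(f"Members: {';'.join(entry.member_ids)}\n")
            if spec.id in comments:
                fh.write(f"Comment: {comments[spec.id]}\n")
            fh.write(f"Num Peaks: {len(spec.peaks)}\n")
            for p in spec.peaks:
                fh.write(f"{p.mz:.{MZ_DECIMALS}f} {p.intensity:.{INTENSITY_DECIMALS}f}\n")
            fh.write("\n")


def read_msp(path: str | Path, sample_id: str | None = None
             ) -> tuple[list[FragmentSpectrum], dict[str, str]]:
    """Parse an MSP file written by :func:`write_msp` (or compatible).

    Returns the spectra and a mapping spectrum id -> Comment string for
    entries that carry one.  Unknown header keys are ignored.
    """
    path = Path(path)
    spectra: list[FragmentSpectrum] = []
    comments: dict[str, str] = {}

    header: dict[str, str] = {}
    peaks: list[Peak] = []
    n_expected: int | None = None

    def flush() -> None:
        nonlocal header, peaks, n_expected
        if not header:
            return
        name = header.get("name", f"entry{len(spectra)}")
        if n_expected is not None and len(peaks) != n_expected:
            raise ValueError(
                f"MSP entry {name!r} in {path} declares {n_expected} peaks "
                f"but has {len(peaks)}")
        spec = FragmentSpectrum(
            id=name,
            sample_id=sample_id if sample_id is not None else header.get("sample", path.stem),
            precursor_mz=float(header.get("precursormz", "0") or 0),
            rt=float(header.get("retentiontime", "0") or 0),
            peaks=tuple(peaks),
            charge=int(header["charge"]) if "charge" in header else None,
            collision_energy=float(header["collisionenergy"]) if "collisionenergy" in header else None,
        )
        spectra.append(spec)
        if "comment" in header:
            comments[name] = header["comment"]
        header, peaks, n_expected = {}, [], None

    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush()
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                key = key.strip().lower().replace(" ", "")
                value = value.strip()
                if key == "numpeaks":
                    n_expected = int(value)
                else:
                    header[key] = value
            else:
                parts = line.replace("\t", " ").split()
                if len(parts) >= 2:
                    peaks.append(Peak(float(parts[0]), float(parts[1])))
    flush()
    return spectra, comments


# ---------------------------------------------------------------------------
# Merging and filtering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # anchor to the smaller root index for order-independence
            if ri < rj:
                self.parent[rj] = ri
            else:
                self.parent[ri] = rj


def merge_spectra(spectra: Sequence[FragmentSpectrum], mz_tol: float = MZ_TOL,
                  rt_tol: float = RT_TOL, bin_width: float = 0.01) -> list[MergedSpectrum]:
    """Merge replicate fragmentation events of one sample.

    Spectra are partitioned into connected components of the graph joining
    pairs with ``|Δprecursor_mz| <= mz_tol`` and ``|Δrt| <= rt_tol``
    (single linkage, so chains merge transitively).  Each component yields
    one consensus spectrum: precursor m/z and retention time are
    intensity-weighted means of the members (weight = total peak intensity,
    falling back to unweighted when all members are empty), and fragment
    peaks are pooled and re-binned at ``bin_width`` Da keeping the maximum
    member intensity per bin.

    The output is deterministic and invariant under permutation of the
    input: components are emitted sorted by (precursor m/z, rt) and member
    ids sorted lexicographically.
    """
    if not spectra:
        return []
    # sort indices by (mz, rt, id) so neighbour search and output order are
    # independent of input order
    order = sorted(range(len(spectra)),
                   key=lambda i: (spectra[i].precursor_mz, spectra[i].rt, spectra[i].id))
    uf = _UnionFind(len(spectra))
    mzs = [spectra[i].precursor_mz for i in order]
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            if mzs[b] - mzs[a] > mz_tol:
                break
            ia, ib = order[a], order[b]
            if abs(spectra[ia].rt - spectra[ib].rt) <= rt_tol:
                uf.union(ia, ib)

    groups: dict[int, list[int]] = {}
    for i in range(len(spectra)):
        groups.setdefault(uf.find(i), []).append(i)

    merged = [_consensus([spectra[i] for i in members], bin_width)
              for members in groups.values()]
    merged.sort(key=lambda m: (m.precursor_mz, m.rt, m.id))
    return merged


def _consensus(members: list[FragmentSpectrum], bin_width: float) -> MergedSpectrum:
    members = sorted(members, key=lambda s: s.id)
    if len(members) == 1:
        return MergedSpectrum(representative=members[0], member_ids=(members[0].id,))

    weights = np.array([sum(p.intensity for p in s.peaks) for s in members])
    if weights.sum() <= 0:
        weights = np.ones(len(members))
    weights = weights / weights.sum()
    prec = float(np.dot(weights, [s.precursor_mz for s in members]))
    rt = float(np.dot(weights, [s.rt for s in members]))

    # pool peaks, re-bin at bin_width, keep the strongest evidence per bin
    bins: dict[int, Peak] = {}
    for s in members:
        for p in s.peaks:
            b = math.floor(p.mz / bin_width)
            if b not in bins or p.intensity > bins[b].intensity:
                bins[b] = p
    peaks = tuple(bins[b] for b in sorted(bins))

    rep = FragmentSpectrum(
        id=members[0].id,
        sample_id=members[0].sample_id,
        precursor_mz=prec,
        rt=rt,
        peaks=peaks,
        charge=members[0].charge,
        collision_energy=members[0].collision_energy,
    )
    return MergedSpectrum(representative=rep, member_ids=tuple(s.id for s in members))


def filter_spectra(spectra: Sequence[MergedSpectrum],
                   mass_range: tuple[float, float] = MASS_RANGE,
                   rt_range: tuple[float, float] = RT_RANGE) -> list[MergedSpectrum]:
    """Keep spectra inside the evaluated precursor-mass and RT windows.

    Bounds are inclusive on both ends; input order is preserved.
    """
    lo_m, hi_m = mass_range
    lo_t, hi_t = rt_range
    kept = [s for s in spectra
            if lo_m <= s.precursor_mz <= hi_m and lo_t <= s.rt <= hi_t]
    logger.info("filter_spectra: kept %d of %d spectra", len(kept), len(spectra))
    return kept


def extract_sample(path: str | Path, sample_id: str | None = None,
                   mz_tol: float = MZ_TOL, rt_tol: float = RT_TOL,
                   mass_range: tuple[float, float] = MASS_RANGE,
                   rt_range: tuple[float, float] = RT_RANGE) -> list[MergedSpectrum]:
    """Read one sample's mzML and return its merged, filtered MS2 spectra."""
    raw = read_mzml(path, sample_id=sample_id)
    merged = merge_spectra(raw, mz_tol=mz_tol, rt_tol=rt_tol)
    kept = filter_spectra(merged, mass_range=mass_range, rt_range=rt_range)
    logger.info("extract %s: %d MS2 scans -> %d merged -> %d in window",
                path, len(raw), len(merged), len(kept))
    return kept
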