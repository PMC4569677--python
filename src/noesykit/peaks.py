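"""Data model and I/O for 3D NOESY peak lists.

A 3D NOESY cross-peak carries three chemical-shift coordinates — the heavy
nucleus (13C or 15N), the proton bound to it, and the NOE-correlated proton —
plus a signed intensity (volume or height).  Which physical dimension plays
which role varies between spectrometers and processing pipelines, so the role
of each column is declared explicitly (file metadata or reader arguments)
rather than guessed.

Two on-disk dialects are supported:

* ``tsv`` — a tab-separated table with header
  ``#id<TAB>shift_heavy<TAB>shift_h_attached<TAB>shift_h_noe<TAB>intensity``,
  ``#`` comment lines, and optional ``#%key=value`` metadata lines carrying
  nucleus types and assignment tolerances.  Round-trips bit-identically.
* ``xeasy`` — a minimal XEASY-compatible subset: whitespace-separated columns
  ``id w1 w2 w3 color intensity``; anything after the intensity is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Peak",
    "PeakList",
    "DEFAULT_TOLERANCES",
    "read_peaklist",
    "write_peaklist",
    "project_to_2d",
]

#: Conventional per-nucleus assignment tolerances (ppm) used when a list
#: declares none.  Fully overridable per list.
DEFAULT_TOLERANCES: dict[str, float] = {"H": 0.02, "C": 0.2, "N": 0.2}

_VALID_NUCLEI = frozenset({"H", "C", "N"})


@dataclass
class Peak:
    """One 3D NOESY cross-peak.

    Parameters
    ----------
    id : int
        Integer label, unique within its list.
    shift_heavy, shift_h_attached, shift_h_noe : float
        Chemical shifts in ppm of the heavy nucleus, the proton bound to it,
        and the NOE-correlated proton.
    intensity : float
        Signed peak volume or height.
    flags : set of str
        Provenance / filter marks (e.g. the label a filter stamped on it).
    """

    id: int
    shift_heavy: float
    shift_h_attached: float
    shift_h_noe: float
    intensity: float
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in ("shift_heavy", "shift_h_attached", "shift_h_noe", "intensity"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"peak {self.id}: {name} is not finite")

    @property
    def shifts(self) -> tuple[float, float, float]:
        return (self.shift_heavy, self.shift_h_attached, self.shift_h_noe)


@dataclass
class PeakList:
    """An ordered collection of peaks with per-nucleus tolerances.

    ``nucleus_types`` names the nucleus of each dimension in the fixed
    internal order (heavy, attached-H, NOE-H); exactly two dimensions must be
    protons.  ``tolerances`` maps nucleus tag to assignment tolerance in ppm.
    """

    peaks: list[Peak] = field(default_factory=list)
    nucleus_types: tuple[str, str, str] = ("C", "H", "H")
    tolerances: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TOLERANCES))
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.nucleus_types) != 3:
            raise ValueError("nucleus_types must have exactly three entries")
        if any(n not in _VALID_NUCLEI for n in self.nucleus_types):
            raise ValueError(f"unknown nucleus tag in {self.nucleus_types}")
        if sum(1 for n in self.nucleus_types if n == "H") != 2:
            raise ValueError("exactly two dimensions must be protons")
        for nuc, tol in self.tolerances.items():
            if not tol > 0:
                raise ValueError(f"tolerance for {nuc} must be strictly positive")
        seen: set[int] = set()
        for p in self.peaks:
            if p.id in seen:
                raise ValueError(f"duplicate peak id {p.id}")
            seen.add(p.id)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def tolerance_for_dimension(self, dim: int) -> float:
        """Assignment tolerance (ppm) of dimension ``dim`` (0=heavy, 1, 2)."""
        nuc = self.nucleus_types[dim]
        try:
            return self.tolerances[nuc]
        except KeyError:
            return DEFAULT_TOLERANCES[nuc]

    def with_peaks(self, peaks: Iterable[Peak]) -> "PeakList":
        """A copy of this list holding ``peaks`` but the same metadata."""
        return replace(self, peaks=list(peaks))

    def intensities(self) -> list[float]:
        return [p.intensity for p in self.peaks]


class PeakListParseError(ValueError):
    """Malformed peak-list row; message carries the 1-based line number."""


_TSV_HEADER = "#id\tshift_heavy\tshift_h_attached\tshift_h_noe\tintensity"


def read_peaklist(path: str | Path, dialect: str = "tsv") -> PeakList:
    """Read a peak list from ``path`` in the given dialect.

    Comment lines (leading ``#``) are skipped; ``#%key=value`` metadata lines
    in the TSV dialect set ``nucleus_types``, ``tolerances`` and ``source``.
    Row order is preserved.
    """
    path = Path(path)
    if dialect not in ("tsv", "xeasy"):
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    nucleus_types: tuple[str, str, str] = ("C", "H", "H")
    tolerances = dict(DEFAULT_TOLERANCES)
    source = str(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#%"):
                key, _, value = line[2:].partition("=")
                key = key.strip()
                value = value.strip()
                if key == "nucleus_types":
                    parts = tuple(v.strip() for v in value.split(","))
                    if len(parts) != 3:
                        raise PeakListParseError(
                            f"{path}:{lineno}: nucleus_types needs 3 entries"
                        )
                    nucleus_types = parts  # type: ignore[assignment]
                elif key == "tolerances":
                    try:
                        for item in value.split(","):
                            nuc, _, tol = item.partition(":")
                            tolerances[nuc.strip()] = float(tol)
                    except ValueError as exc:
                        raise PeakListParseError(
                            f"{path}:{lineno}: bad tolerance spec {value!r}"
                        ) from exc
                elif key == "source":
                    source = value
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t") if dialect == "tsv" else line.split()
            try:
                if dialect == "tsv":
                    if len(fields) != 5:
                        raise ValueError(f"expected 5 columns, got {len(fields)}")
                    pid = int(fields[0])
                    w1, w2, w3, inten = (float(f) for f in fields[1:5])
                else:  # xeasy: id w1 w2 w3 color intensity [ignored...]
                    if len(fields) < 6:
                        raise ValueError(f"expected >= 6 columns, got {len(fields)}")
                    pid = int(fields[0])
                    w1, w2, w3 = (float(f) for f in fields[1:4])
                    inten = float(fields[5])
            except ValueError as exc:
                raise PeakListParseError(f"{path}:{lineno}: malformed row: {exc}") from exc
            peaks.append(Peak(pid, w1, w2, w3, inten))
    return PeakList(peaks=peaks, nucleus_types=nucleus_types, tolerances=tolerances, source=source)


def write_peaklist(pl: PeakList, path: str | Path, dialect: str = "tsv") -> None:
    """Write ``pl`` to ``path``.

    The TSV dialect stores list metadata in ``#%`` lines and float fields via
    ``repr`` so that ``read_peaklist(write_peaklist(pl))`` reproduces every
    field bit-identically.  XEASY output uses a fixed ``0`` colour code.
    """
    path = Path(path)
    if dialect not in ("tsv", "xeasy"):
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    lines: list[str] = []
    if dialect == "tsv":
        lines.append(f"#%nucleus_types={','.join(pl.nucleus_types)}")
        tol = ",".join(f"{nuc}:{val!r}" for nuc, val in sorted(pl.tolerances.items()))
        lines.append(f"#%tolerances={tol}")
        if pl.source:
            lines.append(f"#%source={pl.source}")
        lines.append(_TSV_HEADER)
        for p in pl.peaks:
            lines.append(
                f"{p.id}\t{p.shift_heavy!r}\t{p.shift_h_attached!r}"
                f"\t{p.shift_h_noe!r}\t{p.intensity!r}"
            )
    else:
        lines.append("# id w1 w2 w3 color intensity")
        for p in pl.peaks:
            lines.append(
                f"{p.id:>6d} {p.shift_heavy:9.3f} {p.shift_h_attached:9.3f} "
                f"{p.shift_h_noe:9.3f} 0 {p.intensity:.6e}"
            )
    path.write_text("\n".join(lines) + "\n")


def project_to_2d(pl: PeakList) -> list[tuple[float, float]]:
    """Project every peak onto the heteronuclear correlation (HSQC/HMQC) plane.

    Drops the NOE-proton dimension, keeping ``(shift_heavy, shift_h_attached)``
    — one point per peak, in list order.
    """
    if not pl.peaks:
        raise ValueError("cannot project an empty peak list")
    return [(p.shift_heavy, p.shift_h_attached) for p in pl.peaks]
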