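"""UCSC wiggle (wiggle_0, variableStep span=1) export and re-import.

Zero-valued bases are suppressed, positions are 1-based, and chromosome
names can be remapped at serialization time via a two-column mapping file
(the internal names are never touched).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .signalmap import CoverageTrack


class WiggleError(ValueError):
    pass


class ChromNameMap:
    """Internal-name -> output-name mapping; identity for unmapped names."""

    def __init__(self, entries: Mapping[str, str] | None = None) -> None:
        self.entries = dict(entries or {})
        outputs = list(self.entries.values())
        if len(set(outputs)) != len(outputs):
            raise WiggleError(f"chromosome name map has colliding output names: {outputs}")

    def __getitem__(self, name: str) -> str:
        return self.entries.get(name, name)

    @classmethod
    def from_file(cls, path: str | Path) -> "ChromNameMap":
        entries = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 2:
                    raise WiggleError(f"name-map line needs two columns: {line!r}")
                entries[parts[0]] = parts[1]
        return cls(entries)


def _format_value(v: float) -> str:
    f = float(v)
    if f == int(f):
        return str(int(f))
    return f"{f:.4f}".rstrip("0").rstrip(".")


def write_wiggle(
    tracks: Sequence[CoverageTrack] | Mapping[str, CoverageTrack],
    path: str | Path,
    track_name: str = "coverage",
    name_map: ChromNameMap | None = None,
) -> None:
    """Write tracks as a wiggle_0 file, one variableStep block per chromosome.

    Positions are 1-based, zero values skipped; reals get up to 4 decimals,
    integers no decimal point.  Track order follows the input order, so the
    output is byte-deterministic for a fixed input.
    """
    if isinstance(tracks, Mapping):
        tracks = list(tracks.values())
    name_map = name_map or ChromNameMap()
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        for track in tracks:
            fh.write(f"variableStep chrom={name_map[track.chrom]} span=1\n")
            values = np.asarray(track.values)
            (nz,) = np.nonzero(values)
            for off in nz:
                pos = track.start + int(off) + 1  # 1-based
                fh.write(f"{pos} {_format_value(values[off])}\n")


def read_wiggle(path: str | Path) -> dict[str, CoverageTrack]:
    """Inverse of :func:`write_wiggle` up to zero-valued bases.

    Only the variableStep span=1 dialect is supported.  Each chromosome
    becomes a track starting at its first nonzero base.
    """
    data: dict[str, dict[int, float]] = {}
    chrom: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                raise WiggleError(f"line {lineno}: fixedStep dialect not supported")
            if line.startswith("variableStep"):
                attrs = dict(
                    tok.split("=", 1) for tok in line.split()[1:] if "=" in tok
                )
                if "chrom" not in attrs:
                    raise WiggleError(f"line {lineno}: variableStep without chrom")
                if int(attrs.get("span", 1)) != 1:
                    raise WiggleError(f"line {lineno}: span != 1 not supported")
                chrom = attrs["chrom"]
                data.setdefault(chrom, {})
                continue
            if chrom is None:
                raise WiggleError(f"line {lineno}: data before any variableStep header")
            parts = line.split()
            if len(parts) != 2:
                raise WiggleError(f"line {lineno}: malformed data line {line!r}")
            try:
                pos, value = int(parts[0]), float(parts[1])
            except ValueError as exc:
                raise WiggleError(f"line {lineno}: malformed data line {line!r}") from exc
            data[chrom][pos - 1] = value  # back to 0-based

    tracks: dict[str, CoverageTrack] = {}
    for chrom, points in data.items():
        if not points:
            continue
        start, end = min(points), max(points) + 1
        values = np.zeros(end - start, dtype=np.float64)
        for pos, value in points.items():
            values[pos - start] = value
        if np.all(values == np.round(values)):
            values = values.astype(np.int64)
        tracks[chrom] = CoverageTrack(chrom, start, values)
    return tracks
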