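"""Alignment writers (FASTA, sequential relaxed PHYLIP) with optional gzip.

Writers are byte-deterministic (gzip streams carry a zeroed mtime) and can
stream rows one at a time so that at most one alignment is held in memory.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "OutputSpec",
    "FastaWriter",
    "PhylipWriter",
    "write_fasta",
    "write_phylip",
    "alignment_path",
]

_FASTA_WRAP = 80


@dataclass(frozen=True)
class OutputSpec:
    """Where and how alignments are written."""

    path_prefix: str
    fmt: str = "fasta"            # "fasta" | "phylip"
    gzip_out: bool = False
    n_alignments: int = 1

    def __post_init__(self) -> None:
        if self.fmt not in ("fasta", "phylip"):
            raise ValueError(f"unknown output format {self.fmt!r}")
        if self.n_alignments < 1:
            raise ValueError("n_alignments must be >= 1")


def alignment_path(spec: OutputSpec, index: int) -> Path:
    """File path for replicate ``index`` (1-based); zero-padded suffix when
    more than one alignment is produced."""
    ext = ".fa" if spec.fmt == "fasta" else ".phy"
    if spec.gzip_out:
        ext += ".gz"
    if spec.n_alignments == 1:
        return Path(spec.path_prefix + ext)
    width = max(3, len(str(spec.n_alignments)))
    return Path(f"{spec.path_prefix}_{index:0{width}d}{ext}")


def _open_out(path, gzip_out: bool):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    raw = open(path, "wb")
    if gzip_out:
        # fixed mtime and blank embedded filename keep output byte-deterministic
        return gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0), raw
    return raw, raw


class _BaseWriter:
    def __init__(self, path, gzip_out: bool = False) -> None:
        self._fh, self._raw = _open_out(path, gzip_out)
        self._names: set[str] = set()
        self._width: int | None = None
        self.n_rows = 0

    def _check_row(self, name: str, seq: str) -> None:
        if not name:
            raise ValueError("sequence name must be non-empty")
        if name in self._names:
            raise ValueError(f"duplicate sequence name {name!r}")
        self._names.add(name)
        if self._width is None:
            self._width = len(seq)
        elif len(seq) != self._width:
            raise ValueError("all alignment rows must have equal length")

    def close(self) -> None:
        if self.n_rows == 0:
            self._fh.close()
            if self._fh is not self._raw:
                self._raw.close()
            raise ValueError("refusing to write an empty alignment")
        self._fh.close()
        if self._fh is not self._raw:
            self._raw.close()

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is None:
            self.close()
        else:  # best effort on error paths
            self._fh.close()
            if self._fh is not self._raw:
                self._raw.close()
        return False


class FastaWriter(_BaseWriter):
    """Streaming FASTA writer, 80-column wrapped."""

    def write_row(self, name: str, seq: str) -> None:
        self._check_row(name, seq)
        chunks = [seq[i:i + _FASTA_WRAP] for i in range(0, len(seq), _FASTA_WRAP)]
        self._fh.write((">" + name + "\n" + "\n".join(chunks) + "\n").encode())
        self.n_rows += 1


class PhylipWriter(_BaseWriter):
    """Sequential relaxed PHYLIP: names padded to >= 10 characters; longer
    names are kept intact with a single-space separator."""

    def __init__(self, path, gzip_out: bool = False) -> None:
        super().__init__(path, gzip_out)
        self._started = False
        self._expected = None

    def start(self, n_rows: int, n_sites: int) -> None:
        if self._started:
            raise RuntimeError("PHYLIP header already written")
        self._fh.write(f" {n_rows} {n_sites}\n".encode())
        self._started = True
        self._expected = n_rows
        self._width = n_sites

    def write_row(self, name: str, seq: str) -> None:
        if not self._started:
            raise RuntimeError("call start(n_rows, n_sites) before writing rows")
        self._check_row(name, seq)
        label = name.ljust(10) if len(name) < 10 else name
        self._fh.write((label + " " + seq + "\n").encode())
        self.n_rows += 1

    def close(self) -> None:
        if self._expected is not None and self.n_rows != self._expected:
            raise ValueError(f"wrote {self.n_rows} rows, header promised "
                             f"{self._expected}")
        super().close()


def write_fasta(rows, path, gzip_out: bool = False) -> Path:
    """Write (name, sequence) pairs as wrapped FASTA; returns the path."""
    with FastaWriter(path, gzip_out=gzip_out) as w:
        for name, seq in rows:
            w.write_row(name, seq)
    return Path(path)


def write_phylip(rows, path, gzip_out: bool = False) -> Path:
    rows = list(rows)
    if not rows:
        raise ValueError("refusing to write an empty alignment")
    with PhylipWriter(path, gzip_out=gzip_out) as w:
        w.start(len(rows), len(rows[0][1]))
        for name, seq in rows:
            w.write_row(name, seq)
    return Path(path)
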