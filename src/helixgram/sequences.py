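"""Helix-pair sequence container and bracketed/FASTA-pair I/O.

A helix pair is two short transmembrane helix fragments (10 residues each
by default) whose contact-site configuration is to be classified.  The
canonical string encoding is ``[h1]{h2}``: square brackets delimit the
first helix, curly braces the second.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .grammar import AA_ALPHABET

__all__ = ["HelixPairSequence", "read_pairs", "write_pairs", "PairFormatError"]

_AA_SET = frozenset(AA_ALPHABET)
_BRACKETED_RE = re.compile(r"^\[([A-Z]*)\]\{([A-Z]*)\}$")


class PairFormatError(ValueError):
    """Raised for malformed bracketed strings or unpaired FASTA records."""


@dataclass(frozen=True)
class HelixPairSequence:
    """One helix pair: identifier, the two fragments, optional class label."""

    id: str
    helix1: str
    helix2: str
    label: str | None = None

    def __post_init__(self) -> None:
        for helix in (self.helix1, self.helix2):
            bad = set(helix) - _AA_SET
            if bad:
                raise PairFormatError(
                    f"{self.id}: non-standard residue symbols {sorted(bad)}"
                )

    @property
    def encoded(self) -> str:
        """The bracketed string ``[h1]{h2}``."""
        return f"[{self.helix1}]{{{self.helix2}}}"

    @property
    def residues(self) -> str:
        """Both helices' residues, brackets stripped."""
        return self.helix1 + self.helix2

    @classmethod
    def from_encoded(cls, text: str, id: str = "", label: str | None = None) -> "HelixPairSequence":
        m = _BRACKETED_RE.match(text.strip())
        if not m:
            raise PairFormatError(f"not a bracketed helix pair: {text!r}")
        return cls(id=id or text.strip(), helix1=m.group(1), helix2=m.group(2), label=label)


def write_pairs(dataset: Sequence[HelixPairSequence], path, format: str = "bracketed") -> None:
    """Write pairs as bracketed lines or as paired FASTA records (``/1``, ``/2``).

    The bracketed format is ``id<TAB>[h1]{h2}<TAB>label`` (label column
    omitted when absent); the FASTA format emits two records per pair with
    id suffixes ``/1`` and ``/2`` and the label appended after a space.
    """
    if format == "bracketed":
        with open(path, "w") as fh:
            for seq in dataset:
                cols = [seq.id, seq.encoded]
                if seq.label is not None:
                    cols.append(seq.label)
                fh.write("\t".join(cols) + "\n")
    elif format == "fasta_pairs":
        with open(path, "w") as fh:
            for seq in dataset:
                tag = f" {seq.label}" if seq.label is not None else ""
                fh.write(f">{seq.id}/1{tag}\n{seq.helix1}\n")
                fh.write(f">{seq.id}/2{tag}\n{seq.helix2}\n")
    else:
        raise ValueError(f"unknown pair format {format!r}")


def read_pairs(path, format: str | None = None) -> list[HelixPairSequence]:
    """Read a helix-pair file; the format is sniffed unless given.

    ``read_pairs(write_pairs(ds, p), p)`` is the identity on datasets.
    """
    with open(path) as fh:
        text = fh.read()
    if format is None:
        format = "fasta_pairs" if text.lstrip().startswith(">") else "bracketed"
    if format == "bracketed":
        return _read_bracketed(text, path)
    if format == "fasta_pairs":
        return _read_fasta_pairs(text, path)
    raise ValueError(f"unknown pair format {format!r}")


def _read_bracketed(text: str, path) -> list[HelixPairSequence]:
    out: list[HelixPairSequence] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) == 1:
            ident, encoded, label = "", cols[0], None
        elif len(cols) == 2:
            ident, encoded, label = cols[0], cols[1], None
        else:
            ident, encoded, label = cols[0], cols[1], cols[2]
        try:
            out.append(HelixPairSequence.from_encoded(encoded, id=ident, label=label))
        except PairFormatError as exc:
            raise PairFormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def _read_fasta_pairs(text: str, path) -> list[HelixPairSequence]:
    records: list[tuple[str, str | None, str]] = []  # (id-with-suffix, label, seq)
    header: tuple[str, str | None] | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is not None:
            records.append((header[0], header[1], "".join(chunks)))

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            fields = line[1:].split(None, 1)
            header = (fields[0], fields[1] if len(fields) > 1 else None)
            chunks = []
        else:
            chunks.append(line)
    flush()

    halves: dict[str, dict[str, tuple[str | None, str]]] = {}
    order: list[str] = []
    for full_id, label, seq in records:
        if "/" not in full_id:
            raise PairFormatError(f"{path}: record {full_id!r} lacks a /1 or /2 suffix")
        base, _, suffix = full_id.rpartition("/")
        if suffix not in {"1", "2"}:
            raise PairFormatError(f"{path}: record {full_id!r} has suffix /{suffix}, expected /1 or /2")
        if base not in halves:
            halves[base] = {}
            order.append(base)
        halves[base][suffix] = (label, seq)
    out: list[HelixPairSequence] = []
    for base in order:
        got = halves[base]
        if set(got) != {"1", "2"}:
            raise PairFormatError(f"{path}: unpaired FASTA record for id {base!r}")
        label = got["1"][0] or got["2"][0]
        out.append(HelixPairSequence(id=base, helix1=got["1"][1], helix2=got["2"][1], label=label))
    return out


def iter_residues(sequences: Iterable[HelixPairSequence]) -> Iterable[str]:
    for seq in sequences:
        yield from seq.residues
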