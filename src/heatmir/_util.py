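"""Shared sequence helpers and small I/O utilities."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (T-form)."""
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def to_rna(seq: str) -> str:
    """DNA (T-form) to RNA (U-form), uppercase."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """RNA (U-form) to DNA (T-form), uppercase."""
    return seq.upper().replace("U", "T")


def spawn_rng(seed: int, *keys) -> np.random.Generator:
    """Derive an independent, reproducible generator from a base seed and
    a tuple of hashable keys (library ids, stage names, ...)."""
    material = repr((int(seed),) + tuple(keys)).encode()
    child = int.from_bytes(hashlib.sha256(material).digest()[:4], "big")
    return np.random.default_rng(child)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {full_header: sequence} preserving order.

    Raises ValueError naming the offending line on malformed input.
    """
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].strip()
                if not name:
                    raise ValueError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise ValueError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                chunks.append(line.strip().upper())
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_fasta(path: str | Path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
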