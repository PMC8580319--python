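"""MEME minimal motif text format (version 4) and FASTA I/O helpers."""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from acsarch.motifs import (
    AA_ALPHABET,
    BackgroundModel,
    MotifModel,
    MotifError,
    motif_from_probabilities,
)


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; wrapped or single-line records, '*' stops stripped.

    Raises :class:`MotifError` on duplicate ids, naming the duplicates.
    """
    records = [(r.id, str(r.seq).replace("*", "").upper())
               for r in SeqIO.parse(str(path), "fasta")]
    seen: dict[str, int] = {}
    for rid, _ in records:
        seen[rid] = seen.get(rid, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise MotifError(f"duplicate sequence ids in {path}: {dups}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_meme(motifs: Iterable[MotifModel], path,
               background: BackgroundModel | None = None) -> None:
    """Write motifs in MEME minimal text format (version 4)."""
    motifs = list(motifs)
    if background is None and motifs:
        background = motifs[0].background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {background.alphabet}\n\n")
        fh.write("Background letter frequencies\n")
        parts = [f"{a} {f:.6f}" for a, f in
                 zip(background.alphabet, background.frequencies)]
        fh.write(" ".join(parts) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= {len(m.alphabet)} "
                f"w= {m.width} nsites= {m.nsites:g} E= 0\n"
            )
            for row in m.probabilities:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path, background: BackgroundModel | None = None,
              allow_any_width: bool = False) -> list[MotifModel]:
    """Read motifs from MEME minimal text format.

    If the file carries background letter frequencies they define the
    log-odds null unless an explicit ``background`` overrides them.
    Loaded widths outside [6, 50] require ``allow_any_width``.
    """
    text = Path(path).read_text()
    lines = [ln.rstrip() for ln in text.splitlines()]
    alphabet = AA_ALPHABET
    file_bg: BackgroundModel | None = None
    motifs: list[MotifModel] = []
    i = 0
    if not any(ln.startswith("MEME version") for ln in lines[:5]):
        raise MotifError(f"{path} is not a MEME minimal-format motif file")
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("ALPHABET="):
            alphabet = ln.split("=", 1)[1].strip()
        elif ln.startswith("Background letter frequencies"):
            i += 1
            toks: list[str] = []
            while i < len(lines) and lines[i].strip() and \
                    not lines[i].startswith("MOTIF"):
                toks.extend(lines[i].split())
                i += 1
            freqs = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            arr = np.array([freqs[a] for a in alphabet])
            file_bg = BackgroundModel(arr / arr.sum(), alphabet)
            continue
        elif ln.startswith("MOTIF"):
            motif_id = ln.split()[1]
            i += 1
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            header = lines[i]
            mw = re.search(r"w=\s*(\d+)", header)
            mn = re.search(r"nsites=\s*([\d.eE+-]+)", header)
            width = int(mw.group(1))
            nsites = float(mn.group(1)) if mn else 20.0
            rows = []
            for j in range(width):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            probs = np.asarray(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)
            bg = background or file_bg or BackgroundModel.uniform(alphabet)
            if not allow_any_width and not (6 <= width <= 50):
                raise MotifError(
                    f"motif {motif_id!r} width {width} outside [6, 50]; "
                    "pass allow_any_width=True to load it anyway"
                )
            motifs.append(motif_from_probabilities(probs, bg, motif_id, nsites))
        i += 1
    return motifs
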