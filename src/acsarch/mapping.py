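"""Residue correspondence by global alignment against the AtACS7 reference.

The classification rule anchors two key residues to reference numbering:
the cross-subunit glutamine Q98 (inside ACS motif 2) and the PLP-contacting
asparagine N217.  A query's status at those positions is read off a global
(Needleman-Wunsch, affine-gap) alignment to the reference.  Reference
positions are 1-based and count the initiator Met as residue 1, matching
crystal-structure numbering.

The alignment engine is Biopython's PairwiseAligner; a gap of length k
costs ``gap_open + k * gap_extend`` (BLAST-style, default 11 + k under
BLOSUM62).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


class MappingError(ValueError):
    """Raised for unusable alignment inputs."""


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment as two equal-length gapped strings."""

    query_id: str
    reference_id: str
    aligned_query: str
    aligned_reference: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_reference):
            raise MappingError("aligned strings must have equal length")
        for q, r in zip(self.aligned_query, self.aligned_reference):
            if q == "-" and r == "-":
                raise MappingError("gap-vs-gap column in alignment")

    @property
    def query(self) -> str:
        return self.aligned_query.replace("-", "")

    @property
    def reference(self) -> str:
        return self.aligned_reference.replace("-", "")

    def transposed(self) -> "PairwiseAlignment":
        return PairwiseAlignment(
            query_id=self.reference_id, reference_id=self.query_id,
            aligned_query=self.aligned_reference,
            aligned_reference=self.aligned_query, score=self.score,
        )


@dataclass(frozen=True)
class ResidueCorrespondence:
    """Where one reference residue lands in the query (or None if deleted)."""

    reference_position: int          # 1-based
    reference_residue: str
    query_position: int | None       # 1-based, None when deleted
    query_residue: str | None

    @property
    def deleted(self) -> bool:
        return self.query_position is None


@dataclass(frozen=True)
class KeyResidueStatus:
    """Status of one required residue: match, mismatch(letter), or deleted."""

    status: str                      # "match" | "mismatch" | "deleted"
    required: str
    query_letter: str | None
    query_position: int | None

    @property
    def is_match(self) -> bool:
        return self.status == "match"

    def symbol(self) -> str:
        if self.status == "match":
            return "+"
        if self.status == "deleted":
            return "del"
        return self.query_letter or "-"


@dataclass(frozen=True)
class KeyResidueReport:
    """Per-query statuses of the required reference residues."""

    query_id: str
    statuses: dict[int, KeyResidueStatus]

    @property
    def q98(self) -> KeyResidueStatus:
        return self.statuses[98]

    @property
    def n217(self) -> KeyResidueStatus:
        return self.statuses[217]

    def all_match(self) -> bool:
        return all(s.is_match for s in self.statuses.values())


def _load_matrix(matrix) -> "substitution_matrices.Array":
    if isinstance(matrix, str):
        return substitution_matrices.load(matrix)
    return matrix


def _sanitize(seq: str, alphabet: str) -> str:
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def _gapped_from_coordinates(coords: np.ndarray, a: str, b: str) -> tuple[str, str]:
    ga, gb = [], []
    for k in range(coords.shape[1] - 1):
        a0, a1 = int(coords[0, k]), int(coords[0, k + 1])
        b0, b1 = int(coords[1, k]), int(coords[1, k + 1])
        if a1 > a0 and b1 > b0:
            ga.append(a[a0:a1])
            gb.append(b[b0:b1])
        elif a1 > a0:
            ga.append(a[a0:a1])
            gb.append("-" * (a1 - a0))
        else:
            ga.append("-" * (b1 - b0))
            gb.append(b[b0:b1])
    return "".join(ga), "".join(gb)


def global_align(query: str, reference: str, matrix="BLOSUM62",
                 gap_open: float = 11.0, gap_extend: float = 1.0,
                 query_id: str = "query",
                 reference_id: str = "reference") -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (end gaps penalized).

    Letters absent from the substitution matrix are scored via its X row.
    The pair is aligned in a canonical orientation so that swapping the two
    inputs yields exactly the transposed alignment with the same score.
    """
    if not query or not reference:
        raise MappingError("cannot align an empty sequence")
    mat = _load_matrix(matrix)
    alpha = str(mat.alphabet)
    q = _sanitize(query, alpha)
    r = _sanitize(reference, alpha)

    swap = (r, reference_id) < (q, query_id)
    first, second = (r, q) if swap else (q, r)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(first, second)[0]
    g1, g2 = _gapped_from_coordinates(np.asarray(aln.coordinates), first, second)
    if swap:
        g1, g2 = g2, g1

    # restore original (unsanitized) letters in the gapped strings
    def restore(gapped: str, original: str) -> str:
        out, i = [], 0
        for c in gapped:
            if c == "-":
                out.append("-")
            else:
                out.append(original[i].upper())
                i += 1
        return "".join(out)

    return PairwiseAlignment(
        query_id=query_id, reference_id=reference_id,
        aligned_query=restore(g1, query),
        aligned_reference=restore(g2, reference),
        score=float(aln.score),
    )


def map_reference_position(alignment: PairwiseAlignment,
                           ref_pos: int) -> ResidueCorrespondence:
    """Locate the query residue in the alignment column of reference ``ref_pos``."""
    ref_len = len(alignment.reference)
    if not (1 <= ref_pos <= ref_len):
        raise MappingError(f"ref_pos {ref_pos} out of range 1..{ref_len}")
    seen = 0
    qpos = 0
    for qc, rc in zip(alignment.aligned_query, alignment.aligned_reference):
        if qc != "-":
            qpos += 1
        if rc != "-":
            seen += 1
            if seen == ref_pos:
                if qc == "-":
                    return ResidueCorrespondence(ref_pos, rc, None, None)
                return ResidueCorrespondence(ref_pos, rc, qpos, qc)
    raise AssertionError("unreachable: ref_pos inside validated range")


def check_key_residues(query: str, reference: str | None = None,
                       requirements: dict[int, str] | None = None,
                       query_id: str = "query",
                       **align_kwargs) -> KeyResidueReport:
    """Report match/mismatch/deleted status of each required reference residue.

    Default requirements are {98: 'Q', 217: 'N'}: the cross-subunit
    glutamine and the PLP-contacting asparagine of AtACS7.
    """
    if reference is None:
        _, reference = load_reference()
    if requirements is None:
        requirements = {98: "Q", 217: "N"}
    aln = global_align(query, reference, query_id=query_id, **align_kwargs)
    statuses: dict[int, KeyResidueStatus] = {}
    for pos, required in requirements.items():
        corr = map_reference_position(aln, pos)
        if corr.deleted:
            statuses[pos] = KeyResidueStatus("deleted", required, None, None)
        elif corr.query_residue == required:
            statuses[pos] = KeyResidueStatus("match", required,
                                             corr.query_residue,
                                             corr.query_position)
        else:
            statuses[pos] = KeyResidueStatus("mismatch", required,
                                             corr.query_residue,
                                             corr.query_position)
    return KeyResidueReport(query_id=query_id, statuses=statuses)


class Chimera(str):
    """A domain-swap construct; behaves as a plain sequence string.

    ``provenance`` records the donor/acceptor identities and boundaries,
    mirroring constructs like N7-PpACL1 (an N-terminus grafted onto a
    seven-motif C-terminal backbone).
    """

    provenance: dict

    def __new__(cls, sequence: str, provenance: dict):
        obj = super().__new__(cls, sequence)
        obj.provenance = provenance
        return obj


def make_chimera(n_donor: str, c_acceptor: str, donor_boundary: int,
                 acceptor_boundary: int, donor_id: str = "donor",
                 acceptor_id: str = "acceptor") -> Chimera:
    """Concatenate donor[1..donor_boundary] with acceptor[acceptor_boundary..end].

    Boundaries are 1-based inclusive: ``donor_boundary`` is the last donor
    residue kept, ``acceptor_boundary`` the first acceptor residue kept.
    """
    if not (1 <= donor_boundary <= len(n_donor)):
        raise MappingError(
            f"donor_boundary {donor_boundary} out of range 1..{len(n_donor)}")
    if not (1 <= acceptor_boundary <= len(c_acceptor)):
        raise MappingError(
            f"acceptor_boundary {acceptor_boundary} out of range "
            f"1..{len(c_acceptor)}")
    seq = n_donor[:donor_boundary] + c_acceptor[acceptor_boundary - 1:]
    return Chimera(seq, {
        "donor_id": donor_id,
        "acceptor_id": acceptor_id,
        "donor_boundary": donor_boundary,
        "acceptor_boundary": acceptor_boundary,
    })


def load_reference() -> tuple[str, str]:
    """(id, sequence) of the packaged reference.

    The shipped file is a synthetic stand-in for AtACS7 (TAIR AT4G26200):
    a deterministic protein-like sequence with Q at position 98 and N at
    position 217, so every piece of numbering logic is exercised against
    the real rule even where the database sequence is unavailable.
    """
    path = resources.files("acsarch").joinpath("data/atacs7_synthetic.fasta")
    lines = path.read_text().splitlines()
    rid = lines[0][1:].split()[0]
    seq = "".join(ln.strip() for ln in lines[1:])
    return rid, seq


def report_to_table(reports: list[KeyResidueReport]):
    """Key-residue reports as a DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for rep in reports:
        row = {"query_id": rep.query_id}
        for pos, st in sorted(rep.statuses.items()):
            tag = f"pos{pos}"
            row[f"{tag}_status"] = st.status
            row[f"{tag}_query_letter"] = st.query_letter or ""
            row[f"{tag}_query_pos"] = st.query_position or ""
        rows.append(row)
    return pd.DataFrame(rows)
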