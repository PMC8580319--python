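"""Crystal-structure parsing, least-squares superposition, active-site contacts.

Wraps gemmi for PDB/mmCIF reading, resolves altlocs to a single conformer
(highest occupancy, ties to 'A'), and provides single-pass Kabsch
superposition — no outlier-rejection cycles, so RMSD denominators are
exactly the paired-atom counts reported.  Cross-protein comparisons pair
residues by sequence alignment; within one entry, by residue number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from acsarch.mapping import global_align


class StructureError(ValueError):
    pass


THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F", "GLY": "G",
    "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L", "MET": "M", "ASN": "N",
    "PRO": "P", "GLN": "Q", "ARG": "R", "SER": "S", "THR": "T", "VAL": "V",
    "TRP": "W", "TYR": "Y", "MSE": "M", "SEC": "U", "PYL": "O",
}


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    chain_id: str
    seqnum: int
    icode: str
    name: str
    atoms: dict[str, Atom] = field(default_factory=dict)
    het: bool = False

    @property
    def key(self) -> tuple[int, str]:
        return (self.seqnum, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class StructureModel:
    structure_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    ligands: list[Residue] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chains[chain_id])

    def select(self, selection: str) -> list[Residue]:
        """Parse selections like ``'A'`` or ``'A:10-50'``."""
        m = re.fullmatch(r"(\w+)(?::(-?\d+)-(-?\d+))?", selection)
        if not m:
            raise StructureError(f"cannot parse selection {selection!r}")
        chain, lo, hi = m.group(1), m.group(2), m.group(3)
        if chain not in self.chains:
            raise StructureError(
                f"no chain {chain!r}; available: {sorted(self.chains)}")
        residues = self.chains[chain]
        if lo is not None:
            lo_i, hi_i = int(lo), int(hi)
            residues = [r for r in residues if lo_i <= r.seqnum <= hi_i]
        return residues


def _resolve_altlocs(atom_group: list[Atom]) -> Atom:
    """Highest occupancy wins; ties resolved toward altloc 'A' (then sorted)."""
    return sorted(atom_group, key=lambda a: (-a.occupancy, a.altloc or "A"))[0]


def read_structure(path, fmt: str | None = None,
                   altloc_policy: str = "occupancy",
                   model_index: int = 0) -> StructureModel:
    """Load chains, residues, atoms and het groups from PDB or mmCIF.

    Waters are dropped; non-polymer het residues (e.g. the PLP adduct PPG)
    are collected under ``ligands``.  After altloc resolution each
    (residue, atom-name) keeps exactly one atom.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such coordinate file: {path}")
    if fmt is None:
        st = gemmi.read_structure(str(path))
    else:
        cf = {"pdb": gemmi.CoorFormat.Pdb,
              "mmcif": gemmi.CoorFormat.Mmcif}.get(fmt.lower())
        if cf is None:
            raise StructureError(f"unknown format {fmt!r}")
        st = gemmi.read_structure(str(path), format=cf)
    st.setup_entities()
    if model_index >= len(st):
        raise StructureError(
            f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    out = StructureModel(structure_id=st.name or path.stem)
    for chain in model:
        for res in chain:
            if res.name in ("HOH", "DOD"):
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            groups: dict[str, list[Atom]] = {}
            for atom in res:
                groups.setdefault(atom.name, []).append(Atom(
                    name=atom.name, element=atom.element.name,
                    xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ, altloc=atom.altloc or "",
                ))
            if altloc_policy == "occupancy":
                atoms = {n: _resolve_altlocs(g) for n, g in groups.items()}
            elif altloc_policy == "first":
                atoms = {n: g[0] for n, g in groups.items()}
            else:
                raise StructureError(f"unknown altloc policy {altloc_policy!r}")
            for a in atoms.values():
                if not np.all(np.isfinite(a.xyz)):
                    raise StructureError(
                        f"non-finite coordinates in {chain.name} "
                        f"{res.name}{res.seqid.num}")
            r = Residue(chain_id=chain.name, seqnum=res.seqid.num,
                        icode=res.seqid.icode.strip(), name=res.name,
                        atoms=atoms, het=not is_aa)
            if is_aa:
                out.chains.setdefault(chain.name, []).append(r)
            else:
                out.ligands.append(r)
    return out


def write_pdb(structure: StructureModel, path) -> None:
    """Minimal PDB writer for fixtures (ATOM/HETATM + END)."""
    serial = 1
    with open(path, "w") as fh:
        def emit(res: Residue, record: str):
            nonlocal serial
            for atom in res.atoms.values():
                x, y, z = atom.xyz
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"{record:<6s}{serial:5d} {name:<4s}{'':1s}{res.name:>3s} "
                    f"{res.chain_id:1s}{res.seqnum:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
                serial += 1
        for chain_id in structure.chains:
            for res in structure.chains[chain_id]:
                emit(res, "ATOM")
        for res in structure.ligands:
            emit(res, "HETATM")
        fh.write("END\n")


@dataclass(frozen=True)
class ChainPairing:
    """One-to-one residue pairs with the selected atom present on both sides."""

    mode: str
    pairs: list[tuple[Residue, Residue]]
    atom_set: frozenset[str]
    unpaired_a: int = 0
    unpaired_b: int = 0

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for ra, rb in self.pairs:
            for name in sorted(self.atom_set):
                if name in ra.atoms and name in rb.atoms:
                    xs.append(ra.atoms[name].xyz)
                    ys.append(rb.atoms[name].xyz)
        return np.asarray(xs), np.asarray(ys)


def pair_atoms(selection_a: list[Residue], selection_b: list[Residue],
               mode: str = "by-residue-number",
               atom_set=frozenset({"CA"})) -> ChainPairing:
    """Pair residues between two selections.

    ``by-residue-number`` pairs identical (number, insertion code);
    ``by-sequence-alignment`` pairs via global alignment of the selections'
    one-letter sequences.  Residues lacking the selected atom(s) on either
    side are dropped and counted as unpaired.
    """
    if not selection_a or not selection_b:
        raise StructureError("empty selection")
    atom_set = frozenset(atom_set)

    def has_atoms(r: Residue) -> bool:
        return any(n in r.atoms for n in atom_set)

    raw_pairs: list[tuple[Residue, Residue]] = []
    if mode == "by-residue-number":
        index_b = {r.key: r for r in selection_b}
        for ra in selection_a:
            rb = index_b.get(ra.key)
            if rb is not None:
                raw_pairs.append((ra, rb))
    elif mode == "by-sequence-alignment":
        seq_a = "".join(r.one_letter for r in selection_a)
        seq_b = "".join(r.one_letter for r in selection_b)
        aln = global_align(seq_a, seq_b)
        ia = ib = 0
        for ca, cb in zip(aln.aligned_query, aln.aligned_reference):
            if ca != "-" and cb != "-":
                raw_pairs.append((selection_a[ia], selection_b[ib]))
            if ca != "-":
                ia += 1
            if cb != "-":
                ib += 1
    else:
        raise StructureError(f"unknown pairing mode {mode!r}")

    pairs = [(ra, rb) for ra, rb in raw_pairs
             if any(n in ra.atoms and n in rb.atoms for n in atom_set)]
    if not pairs:
        raise StructureError("pairing produced zero residue pairs")
    return ChainPairing(
        mode=mode, pairs=pairs, atom_set=atom_set,
        unpaired_a=len(selection_a) - len(pairs),
        unpaired_b=len(selection_b) - len(pairs),
    )


@dataclass(frozen=True)
class SuperpositionResult:
    """A rigid-body fit: ``rotation @ y + translation`` maps Y onto X."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(x: np.ndarray, y: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rotation+translation of Y onto X (Kabsch).

    Proper rotations only (reflections excluded via the SVD determinant
    correction).  Requires >= 3 non-collinear pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise StructureError(f"coordinate shapes differ: {x.shape} vs {y.shape}")
    n = x.shape[0]
    if n < 3:
        raise StructureError("superposition needs at least 3 atom pairs")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    if np.linalg.matrix_rank(np.vstack([xc, yc]), tol=1e-10) < 2:
        raise StructureError("degenerate (collinear) configuration")
    H = yc.T @ xc
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    Dm = np.diag([1.0, 1.0, sign])
    R = Vt.T @ Dm @ U.T
    t = x.mean(axis=0) - R @ y.mean(axis=0)
    resid = xc - yc @ R.T
    rmsd = float(np.sqrt((resid ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


@dataclass(frozen=True)
class ActiveSiteResidue:
    chain_id: str
    seqnum: int
    name: str
    min_distance: float
    cross_subunit: bool


@dataclass(frozen=True)
class ActiveSiteReport:
    ligand_id: str
    radius: float
    residues: list[ActiveSiteResidue]

    def labels(self) -> set[str]:
        return {f"{r.one_letter_name}{r.seqnum}" for r in self.residues}


def _one_letter(name: str) -> str:
    return THREE_TO_ONE.get(name, "X")


# give ActiveSiteResidue a one-letter view for compact labels like "N217"
ActiveSiteResidue.one_letter_name = property(lambda self: _one_letter(self.name))


def active_site(structure: StructureModel, ligand: str = "PPG",
                radius: float = 4.0,
                ligand_chain: str | None = None) -> ActiveSiteReport:
    """Protein residues with any non-hydrogen atom within ``radius`` of the ligand.

    Residues on a different chain than the ligand are flagged cross-subunit
    (e.g. the Q98 glutamine protruding into the partner subunit's site).
    Raises naming the available het groups if the ligand is absent.
    """
    lig_residues = [r for r in structure.ligands if r.name == ligand and
                    (ligand_chain is None or r.chain_id == ligand_chain)]
    if not lig_residues:
        available = sorted({r.name for r in structure.ligands})
        raise StructureError(
            f"ligand {ligand!r} not found; het groups present: {available}")
    lig_xyz = np.array([a.xyz for r in lig_residues for a in r.atoms.values()
                        if a.element != "H"])
    lig_chains = {r.chain_id for r in lig_residues}
    found: list[ActiveSiteResidue] = []
    for chain_id, residues in structure.chains.items():
        for res in residues:
            xyz = np.array([a.xyz for a in res.atoms.values()
                            if a.element != "H"])
            if len(xyz) == 0:
                continue
            dmin = float(cdist(xyz, lig_xyz).min())
            if dmin <= radius:
                found.append(ActiveSiteResidue(
                    chain_id=chain_id, seqnum=res.seqnum, name=res.name,
                    min_distance=dmin,
                    cross_subunit=chain_id not in lig_chains,
                ))
    return ActiveSiteReport(ligand_id=ligand, radius=radius, residues=found)


def compare_regions(structure_a: StructureModel, structure_b: StructureModel,
                    residues: list[tuple[str, int]], atom_policy: str = "CA",
                    chain_b: str | None = None,
                    frozen_frame: bool = False) -> SuperpositionResult:
    """Superposition restricted to listed residues of structure A.

    ``residues`` are (chain_id, seqnum) in A's numbering; the corresponding
    B residues are found via sequence alignment of each involved chain
    (``chain_b`` overrides the B chain when names differ).  ``atom_policy``
    is ``'CA'`` or ``'sidechain'`` (all non-backbone heavy atoms shared by
    both sides).  ``frozen_frame=True`` skips the fit and reports the RMSD
    in the current frame.
    """
    if not residues:
        raise StructureError("empty residue list")
    xs, ys = [], []
    chains_a = sorted({c for c, _ in residues})
    for ca in chains_a:
        sel_a = structure_a.chains.get(ca)
        if sel_a is None:
            raise StructureError(f"chain {ca!r} missing in {structure_a.structure_id}")
        cb = chain_b or (ca if ca in structure_b.chains
                         else sorted(structure_b.chains)[0])
        pairing = pair_atoms(sel_a, structure_b.chains[cb],
                             mode="by-sequence-alignment",
                             atom_set=frozenset({"CA"}))
        pair_by_key = {ra.key: (ra, rb) for ra, rb in pairing.pairs}
        wanted = [(c, s) for c, s in residues if c == ca]
        for c, s in wanted:
            if (s, "") not in pair_by_key:
                raise StructureError(
                    f"residue {c}{s} unresolvable in both structures")
            ra, rb = pair_by_key[(s, "")]
            if atom_policy == "CA":
                names = ["CA"]
            elif atom_policy == "sidechain":
                backbone = {"N", "CA", "C", "O", "OXT"}
                names = sorted((set(ra.atoms) & set(rb.atoms)) - backbone)
                names = [n for n in names
                         if ra.atoms[n].element != "H"]
            else:
                raise StructureError(f"unknown atom policy {atom_policy!r}")
            for n in names:
                if n in ra.atoms and n in rb.atoms:
                    xs.append(ra.atoms[n].xyz)
                    ys.append(rb.atoms[n].xyz)
    x = np.asarray(xs)
    y = np.asarray(ys)
    if frozen_frame:
        if x.shape != y.shape or len(x) == 0:
            raise StructureError("mismatched region coordinates")
        rmsd = float(np.sqrt(((x - y) ** 2).sum() / len(x)))
        return SuperpositionResult(rotation=np.eye(3),
                                   translation=np.zeros(3), rmsd=rmsd,
                                   n_atoms=len(x))
    return kabsch_superpose(x, y)
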