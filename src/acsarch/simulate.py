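"""Synthetic protein families and coordinate perturbations with full ground truth.

The generator emulates the validation design the classifier was built for:
a family of 400-500-residue proteins in which genuine-ACS positives carry
nine ungapped motifs in a fixed order (with the key glutamine planted in
motif 2 and the key asparagine in motif 7), and each negative class
deviates in exactly its class-defining feature — a missing motif, a
scrambled motif order, a Q->A or N->A substitution, a seven-C-terminal-
motif-only backbone (the moss C-S lyase pattern), or an aminotransferase
control carrying the AAT motif instead of the two N-terminal ACS motifs.
Motif consensus strings are drawn per seed, so nothing depends on any
external motif table.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from acsarch.motifs import (
    AA_ALPHABET,
    ACS_MOTIF_IDS,
    AAT_MOTIF_ID,
    BackgroundModel,
    MotifModel,
    MotifError,
    DEFAULT_PSEUDOCOUNT,
    build_motif_model,
)

NEGATIVE_CLASSES = (
    "missing_motif", "scrambled_order", "q98_mutant", "n217_mutant",
    "seven_motif_only", "aat_control",
)

#: A plant-proteome-like composition (rounded averages over well-annotated
#: plant proteomes), offered as an alternative to the uniform default.
PLANT_COMPOSITION = {
    "A": 0.063, "C": 0.018, "D": 0.054, "E": 0.067, "F": 0.041, "G": 0.064,
    "H": 0.023, "I": 0.053, "K": 0.061, "L": 0.095, "M": 0.024, "N": 0.043,
    "P": 0.048, "Q": 0.035, "R": 0.054, "S": 0.084, "T": 0.050, "V": 0.066,
    "W": 0.012, "Y": 0.045,
}


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic protein family with planted motifs.

    Defaults are the benchmark conditions: 50 positives, 50 negatives spread
    over the six ablation classes, per-column conservation 0.9 over a
    uniform background, spacers geometric with mean 25, sequences ~420-480
    residues.
    """

    n_positive: int = 50
    n_negative_by_class: dict = field(default_factory=lambda: {
        "missing_motif": 15, "scrambled_order": 7, "q98_mutant": 7,
        "n217_mutant": 7, "seven_motif_only": 7, "aat_control": 7,
    })
    length_range: tuple[int, int] = (420, 480)
    motif_widths: tuple[int, ...] = (14, 21, 18, 16, 24, 15, 20, 17, 22)
    aat_width: int = 18
    conservation: float = 0.9
    #: Consensus-level divergence of the seven_motif_only and aat_control
    #: classes from the family consensus.  These stand in for anciently
    #: diverged homologs (C-S lyases, aminotransferases), unlike the four
    #: point-ablation classes which deviate in exactly one feature.
    control_divergence: float = 0.3
    background: BackgroundModel = field(
        default_factory=BackgroundModel.uniform)
    spacer_mean: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.conservation <= 1.0):
            raise MotifError("conservation must lie in [0, 1]")
        if len(self.motif_widths) != 9:
            raise MotifError("exactly nine ACS motif widths are required")
        widths = (*self.motif_widths, self.aat_width)
        if any(not (6 <= w <= 50) for w in widths):
            raise MotifError("motif widths must lie in [6, 50]")
        if any(v < 0 for v in self.n_negative_by_class.values()):
            raise MotifError("negative class counts must be >= 0")
        unknown = set(self.n_negative_by_class) - set(NEGATIVE_CLASSES)
        if unknown:
            raise MotifError(f"unknown negative classes: {sorted(unknown)}")
        # motifs plus minimal spacers must fit the maximum length
        if sum(self.motif_widths) + 10 > self.length_range[1]:
            raise MotifError(
                "planted motifs plus spacers exceed the maximum length")


@dataclass(frozen=True)
class SequenceTruth:
    sequence_id: str
    label: str                       # "positive" or a negative class name
    missing_motif: int | None        # k for the missing_motif class
    planted: dict[str, tuple[int, str]]   # motif_id -> (start_1based, instance)
    q_pos: int | None                # 1-based, None when motif 2 absent
    q_letter: str | None
    n_pos: int | None
    n_letter: str | None

    @property
    def is_positive(self) -> bool:
        return self.label == "positive"


@dataclass(frozen=True)
class GroundTruth:
    """Per-sequence truths plus the family's reference frame."""

    truths: dict[str, SequenceTruth]
    reference_id: str
    reference_sequence: str
    q_position: int                  # key glutamine position in the reference
    n_position: int
    consensus: dict[str, str]        # motif_id -> family consensus string
    q_offset: int                    # 0-based offset of Q inside motif 2
    n_offset: int
    #: diverged per-class consensus for the evolutionary control classes
    class_consensus: dict[str, dict[str, str]] = field(default_factory=dict)

    def labels(self) -> dict[str, bool]:
        return {sid: t.is_positive for sid, t in self.truths.items()}


def _sample_letters(rng, background: BackgroundModel, n: int) -> str:
    idx = rng.choice(len(background.alphabet), size=n,
                     p=background.frequencies)
    return "".join(background.alphabet[i] for i in idx)


def _motif_instance(rng, consensus: str, c: float,
                    background: BackgroundModel,
                    forced: dict[int, str]) -> str:
    out = []
    for i, cons in enumerate(consensus):
        if i in forced:
            out.append(forced[i])
        elif rng.random() < c:
            out.append(cons)
        else:
            out.append(_sample_letters(rng, background, 1))
    return "".join(out)


def _spacer_lengths(rng, n: int, mean: float) -> list[int]:
    # geometric on {1, 2, ...} with the stated mean
    p = 1.0 / max(mean, 1.0)
    return [int(v) for v in rng.geometric(p, size=n)]


def sample_family(spec: FamilySpec) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Generate the family FASTA records and their ground truth.

    Positives carry ACS1..ACS9 in order at geometric spacers; each negative
    class deviates only in its defining feature.  Byte-identical output for
    identical (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    bg = spec.background

    consensus: dict[str, str] = {}
    for mid, w in zip(ACS_MOTIF_IDS, spec.motif_widths):
        consensus[mid] = _sample_letters(rng, bg, w)
    consensus[AAT_MOTIF_ID] = _sample_letters(rng, bg, spec.aat_width)
    q_off = spec.motif_widths[1] // 2
    n_off = spec.motif_widths[6] // 3
    consensus["ACS2"] = (consensus["ACS2"][:q_off] + "Q"
                         + consensus["ACS2"][q_off + 1:])
    consensus["ACS7"] = (consensus["ACS7"][:n_off] + "N"
                         + consensus["ACS7"][n_off + 1:])

    # one family-wide spacer layout (homologs share architecture spacing);
    # each sequence jitters it by small indels below
    family_spacers = _spacer_lengths(rng, 10, spec.spacer_mean)
    lo, hi = spec.length_range
    motif_total9 = sum(len(consensus[m]) for m in ACS_MOTIF_IDS)
    target = int(rng.integers(lo, hi + 1))
    budget = max(target - motif_total9, 10)
    raw_total = sum(family_spacers)
    family_spacers = [max(1, int(s * budget / raw_total))
                      for s in family_spacers]
    family_spacers[-1] += budget - sum(family_spacers)
    family_spacers[-1] = max(family_spacers[-1], 1)

    def diverged_consensus(delta: float, protect: set,
                           local_rng) -> dict[str, str]:
        out = {}
        for mid, cons in consensus.items():
            letters = list(cons)
            for i in range(len(letters)):
                if (mid, i) in protect:
                    continue
                if local_rng.random() < delta:
                    letters[i] = _sample_letters(local_rng, bg, 1)
            out[mid] = "".join(letters)
        return out

    def build_sequence(motif_ids: list[str], c: float,
                       key_overrides: dict[str, dict[int, str]],
                       local_rng, jitter: bool = True,
                       cons_map: dict[str, str] | None = None
                       ) -> tuple[str, dict[str, tuple[int, str]]]:
        if cons_map is None:
            cons_map = consensus
        k = len(motif_ids) + 1
        if k == len(family_spacers):
            spacers = list(family_spacers)
        else:
            # fewer motifs: keep the first spacer, merge the leading unused
            # spacer budget into it, reuse the tail slots
            spacers = list(family_spacers[-k:])
            spacers[0] += sum(family_spacers[:-k])
        if jitter:
            spacers = [max(1, s + int(local_rng.integers(-3, 4)))
                       for s in spacers]
        parts = []
        planted: dict[str, tuple[int, str]] = {}
        pos = 0
        for mid, sp in zip(motif_ids, spacers[:-1]):
            seg = _sample_letters(local_rng, bg, sp)
            parts.append(seg)
            pos += sp
            forced = dict(key_overrides.get(mid, {}))
            inst = _motif_instance(local_rng, cons_map[mid], c, bg, forced)
            parts.append(inst)
            planted[mid] = (pos + 1, inst)   # 1-based
            pos += len(inst)
        parts.append(_sample_letters(local_rng, bg, spacers[-1]))
        return "".join(parts), planted

    # reference: consensus motifs, deterministic spacers from the family rng
    ref_seq, ref_planted = build_sequence(
        list(ACS_MOTIF_IDS), 1.0,
        {"ACS2": {q_off: "Q"}, "ACS7": {n_off: "N"}}, rng, jitter=False)
    q_position = ref_planted["ACS2"][0] + q_off
    n_position = ref_planted["ACS7"][0] + n_off

    # the two evolutionary control classes carry their own diverged consensus
    protect = {("ACS7", n_off)}
    lyase_cons = diverged_consensus(spec.control_divergence, protect, rng)
    aat_cons = diverged_consensus(spec.control_divergence, protect, rng)

    records: list[tuple[str, str]] = []
    truths: dict[str, SequenceTruth] = {}

    def add(sid: str, label: str, motif_ids: list[str],
            key_overrides: dict[str, dict[int, str]],
            missing: int | None = None,
            cons_map: dict[str, str] | None = None) -> None:
        seq, planted = build_sequence(motif_ids, spec.conservation,
                                      key_overrides, rng, cons_map=cons_map)
        qp = ql = npos = nl = None
        if "ACS2" in planted:
            qp = planted["ACS2"][0] + q_off
            ql = seq[qp - 1]
        if "ACS7" in planted:
            npos = planted["ACS7"][0] + n_off
            nl = seq[npos - 1]
        records.append((sid, seq))
        truths[sid] = SequenceTruth(
            sequence_id=sid, label=label, missing_motif=missing,
            planted=planted, q_pos=qp, q_letter=ql, n_pos=npos, n_letter=nl)

    keys_ok = {"ACS2": {q_off: "Q"}, "ACS7": {n_off: "N"}}
    for i in range(spec.n_positive):
        add(f"pos{i:03d}", "positive", list(ACS_MOTIF_IDS), keys_ok)

    counts = spec.n_negative_by_class
    for i in range(counts.get("missing_motif", 0)):
        k = (i % 9) + 1
        ids = [m for m in ACS_MOTIF_IDS if m != f"ACS{k}"]
        add(f"neg_missing{i:03d}", "missing_motif", ids, keys_ok, missing=k)
    for i in range(counts.get("scrambled_order", 0)):
        add(f"neg_scram{i:03d}", "scrambled_order",
            list(reversed(ACS_MOTIF_IDS)), keys_ok)
    for i in range(counts.get("q98_mutant", 0)):
        add(f"neg_q98{i:03d}", "q98_mutant", list(ACS_MOTIF_IDS),
            {"ACS2": {q_off: "A"}, "ACS7": {n_off: "N"}})
    for i in range(counts.get("n217_mutant", 0)):
        add(f"neg_n217{i:03d}", "n217_mutant", list(ACS_MOTIF_IDS),
            {"ACS2": {q_off: "Q"}, "ACS7": {n_off: "A"}})
    for i in range(counts.get("seven_motif_only", 0)):
        add(f"neg_seven{i:03d}", "seven_motif_only",
            [m for m in ACS_MOTIF_IDS if m not in ("ACS1", "ACS2")],
            {"ACS7": {n_off: "N"}}, cons_map=lyase_cons)
    for i in range(counts.get("aat_control", 0)):
        add(f"neg_aat{i:03d}", "aat_control",
            [AAT_MOTIF_ID] + [m for m in ACS_MOTIF_IDS
                              if m not in ("ACS1", "ACS2")],
            {"ACS7": {n_off: "N"}}, cons_map=aat_cons)

    truth = GroundTruth(
        truths=truths, reference_id="family_reference",
        reference_sequence=ref_seq, q_position=q_position,
        n_position=n_position, consensus=consensus,
        q_offset=q_off, n_offset=n_off,
        class_consensus={"seven_motif_only": lyase_cons,
                         "aat_control": aat_cons},
    )
    return records, truth


def family_motif_models(records, truth: GroundTruth,
                        background: BackgroundModel | None = None,
                        pseudocount: float = DEFAULT_PSEUDOCOUNT
                        ) -> dict[str, MotifModel]:
    """Scanning models built from the planted instances across the family.

    Each motif's PWM is estimated from every sequence that truly carries it
    (positives for the nine ACS motifs, aminotransferase controls for AAT),
    which is how models would be built from a curated alignment of known
    family members.
    """
    if background is None:
        background = BackgroundModel.uniform()
    instances: dict[str, list[str]] = {}
    for t in truth.truths.values():
        for mid, (_, inst) in t.planted.items():
            instances.setdefault(mid, []).append(inst)
    models = {}
    for mid, insts in instances.items():
        models[mid] = build_motif_model(insts, background, pseudocount,
                                        motif_id=mid)
    return models


@dataclass(frozen=True)
class CompositionReport:
    n_spacer_letters: int
    chi2_statistic: float | None
    chi2_p_value: float | None
    conservation_estimate: float | None
    conservation_expected: float
    n_planted_columns: int
    notes: list[str]


def empirical_composition_check(records, truth: GroundTruth,
                                spec: FamilySpec) -> CompositionReport:
    """Goodness-of-fit of the generator's own output.

    Spacer letters are tested against the spec background by chi-squared;
    planted (non-forced) motif columns yield a conservation estimate whose
    expectation is c + (1-c) * bg(consensus letter) because the background
    draw may coincide with the consensus.
    """
    bg = spec.background
    seqs = dict(records)
    spacer_counts = np.zeros(len(bg.alphabet))
    idx = {a: i for i, a in enumerate(bg.alphabet)}
    match = 0
    total_cols = 0
    exp_terms = []
    for sid, t in truth.truths.items():
        seq = seqs[sid]
        covered = np.zeros(len(seq), dtype=bool)
        class_cons = truth.class_consensus.get(t.label, truth.consensus)
        for mid, (start1, inst) in t.planted.items():
            s0 = start1 - 1
            covered[s0:s0 + len(inst)] = True
            cons = class_cons[mid]
            forced = set()
            if mid == "ACS2":
                forced.add(truth.q_offset)
            if mid == "ACS7":
                forced.add(truth.n_offset)
            for i, (a, b) in enumerate(zip(inst, cons)):
                if i in forced:
                    continue
                total_cols += 1
                match += a == b
                exp_terms.append(bg[b])
        for i, ch in enumerate(seq):
            if not covered[i] and ch in idx:
                spacer_counts[idx[ch]] += 1

    notes = []
    n_spacer = int(spacer_counts.sum())
    if n_spacer == 0:
        notes.append("zero-length spacers: background composition untestable")
        chi2 = pval = None
    else:
        expected = bg.frequencies * n_spacer
        chi2, pval = stats.chisquare(spacer_counts, expected)
        chi2, pval = float(chi2), float(pval)
    c = spec.conservation
    expected_cons = c + (1 - c) * float(np.mean(exp_terms)) if exp_terms else c
    est = match / total_cols if total_cols else None
    return CompositionReport(
        n_spacer_letters=n_spacer, chi2_statistic=chi2, chi2_p_value=pval,
        conservation_estimate=est, conservation_expected=expected_cons,
        n_planted_columns=total_cols, notes=notes,
    )


# ---------------------------------------------------------------------------
# coordinate perturbations with exact post-superposition RMSD


@dataclass(frozen=True)
class PerturbationSpec:
    target_rmsd: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_rmsd < 0:
            raise MotifError("target rmsd must be >= 0")


def synthetic_chain(n_points: int, seed: int = 0,
                    step: float = 3.8) -> np.ndarray:
    """A self-avoiding-ish random-walk C-alpha trace with ~3.8 A steps."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_points - 1, 3))
    steps *= step / np.linalg.norm(steps, axis=1, keepdims=True)
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


def _rigid_mode_basis(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body modes in 3n space."""
    n = base.shape[0]
    centered = base - base.mean(axis=0)
    modes = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        modes.append(t.ravel())
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        modes.append(np.cross(np.broadcast_to(axis, (n, 3)), centered).ravel())
    Q, _ = np.linalg.qr(np.array(modes).T)
    return Q


def perturb_coordinates(base: np.ndarray,
                        spec: PerturbationSpec) -> np.ndarray:
    """Displace ``base`` so the post-Kabsch RMSD to it equals the target.

    The random displacement field is projected orthogonal to the six
    rigid-body modes, then its amplitude is solved (secant iteration on the
    actually-computed superposition) until the measured RMSD matches the
    target within 1e-9.
    """
    from acsarch.structure import kabsch_superpose

    base = np.asarray(base, dtype=float)
    n = base.shape[0]
    if n < 4:
        raise MotifError("perturbation needs at least 4 points")
    if spec.target_rmsd == 0.0:
        return base.copy()
    rng = np.random.default_rng(spec.seed)
    disp = rng.normal(size=(n, 3))
    Q = _rigid_mode_basis(base)
    v = disp.ravel()
    v -= Q @ (Q.T @ v)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise MotifError("degenerate base: displacement collapses onto rigid modes")
    unit = (v / norm).reshape(n, 3)

    def measured(s: float) -> float:
        return kabsch_superpose(base, base + s * unit).rmsd

    target = spec.target_rmsd
    s = target * np.sqrt(n)
    f = measured(s) - target
    s_prev, f_prev = 0.0, -target
    for _ in range(100):
        if abs(f) <= 1e-12:
            break
        denom = f - f_prev
        step = -f * (s - s_prev) / denom if denom != 0 else -f
        s_prev, f_prev = s, f
        s = s + step
        f = measured(s) - target
    if abs(f) > 1e-9:
        raise MotifError(
            f"could not reach target rmsd {target} (residual {f:.2e})")
    return base + s * unit


def chain_structure(coords: np.ndarray, structure_id: str = "synthetic",
                    chain_id: str = "A"):
    """Wrap a C-alpha trace as a StructureModel of ALA residues (fixtures)."""
    from acsarch.structure import Atom, Residue, StructureModel

    chains = {chain_id: []}
    for i, xyz in enumerate(np.asarray(coords, dtype=float), start=1):
        chains[chain_id].append(Residue(
            chain_id=chain_id, seqnum=i, icode="", name="ALA",
            atoms={"CA": Atom(name="CA", element="C",
                              xyz=np.array(xyz, dtype=float))},
        ))
    return StructureModel(structure_id=structure_id, chains=chains)
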