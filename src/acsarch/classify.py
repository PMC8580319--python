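"""The genuine-ACS decision rule and its evidence matrix.

A sequence is predicted to be a genuine ACS (an ACS-like protein that
actually converts SAM to ACC) iff

* all nine ACS motifs are present, at strictly increasing, non-overlapping
  positions (the ordered architecture), AND
* the glutamine corresponding to Q98 of the reference is present, AND
* the asparagine corresponding to N217 is present.

The N217 conjunct encodes the one documented exception to the motif+Q98
rule (AtACS1: complete architecture and Q98, no activity, missing the
PLP-contacting asparagine).  ``strict_n217=False`` restores the two-level
presentation in which N217 failures are annotated rather than vetoing.
AAT-motif presence is reported as its own column and never vetoes.
Cbeta-S lyase activity is not determined by this model and is reported as
such.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import pandas as pd

from acsarch.motifs import (
    ACS_MOTIF_IDS,
    AAT_MOTIF_ID,
    BackgroundModel,
    MotifModel,
    MotifArchitecture,
    MotifError,
    DEFAULT_P_THRESHOLD,
    scan_sequence,
    score_distribution,
    assess_architecture,
)
from acsarch.mapping import KeyResidueReport, check_key_residues


class ConfigurationError(ValueError):
    """Raised when the motif set or classifier configuration is unusable."""


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping (key order irrelevant)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class ACSClassification:
    """Per-sequence evidence record: one row of the validation matrix."""

    sequence_id: str
    motif_presence: dict[str, bool]     # ACS1..ACS9 and AAT
    ordered: bool
    q98: "KeyResidueStatus"
    n217: "KeyResidueStatus"
    predicted_acs: bool
    exception_notes: list[str]
    architecture: MotifArchitecture
    config_hash: str

    @property
    def aat_present(self) -> bool:
        return self.motif_presence.get(AAT_MOTIF_ID, False)

    def row(self) -> dict:
        row = {"sequence_id": self.sequence_id}
        for m in ACS_MOTIF_IDS:
            row[m] = "+" if self.motif_presence.get(m, False) else "-"
        row[AAT_MOTIF_ID] = "+" if self.aat_present else "-"
        row["ordered"] = "+" if self.ordered else "-"
        row["Q98"] = self.q98.symbol()
        row["N217"] = self.n217.symbol()
        row["predicted_ACS"] = "+" if self.predicted_acs else "-"
        row["CbS_lyase"] = "ND"   # not determined by this model
        row["notes"] = "; ".join(self.exception_notes)
        row["config_hash"] = self.config_hash
        return row


def _prepare_motifs(motif_set) -> dict[str, MotifModel]:
    if isinstance(motif_set, dict):
        models = dict(motif_set)
    else:
        models = {m.motif_id: m for m in motif_set}
    missing = [m for m in ACS_MOTIF_IDS if m not in models]
    if missing:
        raise ConfigurationError(f"motif set is missing required models: {missing}")
    return models


def classify_sequence(sequence: str, motif_set, background: BackgroundModel,
                      reference: str, p_threshold: float = DEFAULT_P_THRESHOLD,
                      q_position: int = 98, n_position: int = 217,
                      strict_n217: bool = True, sequence_id: str = "query",
                      _dists=None, _cfg_hash: str | None = None,
                      **align_kwargs) -> ACSClassification:
    """Scan, assess the ordered architecture, map key residues, apply the rule.

    ``q_position``/``n_position`` give the Q- and N-key-residue positions in
    the reference's own 1-based numbering (98 and 217 for AtACS7).
    """
    models = _prepare_motifs(motif_set)
    if _dists is None:
        _dists = {mid: score_distribution(m, background)
                  for mid, m in models.items()}
    hits = []
    for mid, m in models.items():
        hits.extend(scan_sequence(sequence, m, background, p_threshold,
                                  sequence_id=sequence_id, dist=_dists[mid]))
    arch = assess_architecture(hits)
    if not arch.sequence_id:
        arch = MotifArchitecture(sequence_id=sequence_id,
                                 presence=arch.presence, ordered=arch.ordered,
                                 aat_present=arch.aat_present,
                                 complete=arch.complete)

    residues = check_key_residues(
        sequence, reference,
        requirements={q_position: "Q", n_position: "N"},
        query_id=sequence_id, **align_kwargs)
    q_status = residues.statuses[q_position]
    n_status = residues.statuses[n_position]

    notes: list[str] = []
    motifs_and_q = arch.complete and q_status.is_match
    if motifs_and_q and not n_status.is_match:
        notes.append(
            "meets the nine-motif + Q98 requirements but lacks the "
            "N217-equivalent asparagine (AtACS1-type exception)"
        )
    predicted = motifs_and_q and (n_status.is_match or not strict_n217)

    presence = {m: arch.presence[m] is not None for m in ACS_MOTIF_IDS}
    presence[AAT_MOTIF_ID] = arch.aat_present
    if _cfg_hash is None:
        _cfg_hash = config_hash({
            "p_threshold": p_threshold, "q_position": q_position,
            "n_position": n_position, "strict_n217": strict_n217,
            "motifs": sorted(models), **align_kwargs,
        })
    return ACSClassification(
        sequence_id=sequence_id,
        motif_presence=presence,
        ordered=arch.ordered,
        q98=q_status,
        n217=n_status,
        predicted_acs=predicted,
        exception_notes=notes,
        architecture=arch,
        config_hash=_cfg_hash,
    )


@dataclass(frozen=True)
class EvidenceTable:
    """All per-sequence classifications, renderable as a +/- matrix."""

    classifications: list[ACSClassification]

    def to_frame(self) -> pd.DataFrame:
        cols = (["sequence_id"] + list(ACS_MOTIF_IDS) + [AAT_MOTIF_ID, "ordered",
                "Q98", "N217", "predicted_ACS", "CbS_lyase", "notes",
                "config_hash"])
        return pd.DataFrame([c.row() for c in self.classifications],
                            columns=cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_pretty(self) -> str:
        return self.to_frame().drop(columns=["config_hash"]).to_string(index=False)

    def to_json_report(self) -> dict:
        """Full hit coordinates and p-values per sequence (1-based inclusive)."""
        report = {}
        for c in self.classifications:
            hits = {}
            for mid, h in c.architecture.presence.items():
                hits[mid] = None if h is None else {
                    "start": h.start_1based, "end": h.end_1based,
                    "score_bits": h.score, "p_value": h.p_value,
                }
            report[c.sequence_id] = {
                "predicted_ACS": c.predicted_acs,
                "ordered": c.ordered,
                "q98": asdict(c.q98),
                "n217": asdict(c.n217),
                "hits": hits,
                "notes": c.exception_notes,
                "config_hash": c.config_hash,
            }
        return report


def classify_batch(records, motif_set, background: BackgroundModel,
                   reference: str, p_threshold: float = DEFAULT_P_THRESHOLD,
                   q_position: int = 98, n_position: int = 217,
                   strict_n217: bool = True, **align_kwargs) -> EvidenceTable:
    """Classify every (id, sequence) record; deterministic given config.

    ``records`` may be a FASTA path or an iterable of (id, sequence) pairs.
    Duplicate ids are an error naming the duplicates.  An empty input yields
    an empty table.
    """
    if isinstance(records, (str, bytes)) or hasattr(records, "read_text") \
            or hasattr(records, "__fspath__"):
        from acsarch.meme_io import read_fasta
        records = read_fasta(records)
    records = list(records)
    ids = [r[0] for r in records]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise MotifError(f"duplicate sequence ids: {dups}")

    models = _prepare_motifs(motif_set)
    dists = {mid: score_distribution(m, background) for mid, m in models.items()}
    cfg = config_hash({
        "p_threshold": p_threshold, "q_position": q_position,
        "n_position": n_position, "strict_n217": strict_n217,
        "motifs": sorted(models), **align_kwargs,
    })
    out = [
        classify_sequence(seq, models, background, reference, p_threshold,
                          q_position, n_position, strict_n217,
                          sequence_id=rid, _dists=dists, _cfg_hash=cfg,
                          **align_kwargs)
        for rid, seq in records
    ]
    return EvidenceTable(out)
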