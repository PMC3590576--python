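"""Readers and writers for the plain-text files of the β-turn prediction pipeline.

The pipeline touches five external formats, all line-oriented text:

* FASTA protein chains (read via Biopython);
* PSI-BLAST ASCII profile files, of which only the first 20-column log-odds
  block is consumed;
* a columnar TSV of 3-state secondary-structure predictions
  (``chain_id  source  pos  state  conf``), one row per residue per predictor;
* a labels TSV mapping each chain to its per-residue ``t``/``n`` string;
* a predictions TSV with raw/smoothed labels and turn probabilities.

File positions are 1-based; everything in memory is 0-based.  Readers are
strict: any length mismatch against the chain sequence, alphabet violation or
positional gap raises :class:`FormatError` rather than silently truncating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

#: The 20 standard amino acids (one-letter); ``X`` is additionally accepted
#: in chain sequences for unknown residues.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Column order of the PSI-BLAST ASCII profile score block.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

SS_STATES = "HEC"
TURN_ALPHABET = "tn"


class FormatError(ValueError):
    """An input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ProteinChain:
    """A protein chain: identifier plus uppercase amino-acid sequence."""

    chain_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise FormatError("chain_id must be nonempty")
        self.sequence = self.sequence.upper()
        allowed = set(AMINO_ACIDS + "X")
        for i, ch in enumerate(self.sequence):
            if ch not in allowed:
                raise FormatError(
                    f"chain {self.chain_id!r}: illegal residue {ch!r} at position {i + 1}"
                )
        if not self.sequence:
            raise FormatError(f"chain {self.chain_id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PSSMProfile:
    """L×20 position-specific scoring matrix for one chain.

    ``raw`` holds log-odds scores as produced by iterative profile search;
    ``scaled`` is filled by :func:`turnklr.features.scale_pssm` and lives in
    [0, 1].
    """

    chain_id: str
    raw: np.ndarray
    scaled: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[1] != 20:
            raise FormatError(
                f"PSSM for chain {self.chain_id!r}: expected L×20 matrix, "
                f"got shape {self.raw.shape}"
            )
        if self.scaled is not None:
            self.scaled = np.asarray(self.scaled, dtype=float)
            if self.scaled.shape != self.raw.shape:
                raise FormatError("scaled PSSM shape differs from raw")
            if (self.scaled < 0).any() or (self.scaled > 1).any():
                raise FormatError("scaled PSSM values must lie in [0, 1]")


@dataclass
class SSPrediction:
    """Per-residue 3-state secondary structure from one external predictor.

    ``states`` is a string over ``{H, E, C}``; ``confidence`` holds one 0–9
    digit per residue (higher = more confident).
    """

    chain_id: str
    source: str
    states: str
    confidence: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.states) != len(self.confidence):
            raise FormatError(
                f"SS prediction {self.chain_id}/{self.source}: states and "
                "confidence lengths differ"
            )
        for i, st in enumerate(self.states):
            if st not in SS_STATES:
                raise FormatError(
                    f"SS prediction {self.chain_id}/{self.source}: state {st!r} "
                    f"at position {i + 1} not in {{H,E,C}}"
                )
        conf = list(self.confidence)
        for i, c in enumerate(conf):
            if not (0 <= int(c) <= 9):
                raise FormatError(
                    f"SS prediction {self.chain_id}/{self.source}: confidence "
                    f"{c!r} at position {i + 1} outside 0–9"
                )
        self.confidence = [int(c) for c in conf]

    @property
    def length(self) -> int:
        return len(self.states)


@dataclass
class TurnLabels:
    """Per-residue β-turn labels: ``t`` (turn) / ``n`` (non-turn)."""

    chain_id: str
    labels: str

    def __post_init__(self) -> None:
        for i, ch in enumerate(self.labels):
            if ch not in TURN_ALPHABET:
                raise FormatError(
                    f"labels for {self.chain_id!r}: illegal character {ch!r} "
                    f"at position {i + 1}"
                )


@dataclass
class PredictionRecord:
    """One residue's prediction: probability plus raw and smoothed labels."""

    chain_id: str
    position: int  # 1-based
    probability: float
    raw_label: str
    smoothed_label: str


@dataclass
class Dataset:
    """In-memory bundle of a full annotated dataset.

    ``ss`` maps chain_id → {source → SSPrediction}; ``source_order`` fixes the
    predictor order the feature encoding relies on.
    """

    chains: List[ProteinChain]
    pssms: Dict[str, PSSMProfile]
    ss: Dict[str, Dict[str, SSPrediction]]
    labels: Dict[str, TurnLabels] = field(default_factory=dict)
    source_order: Tuple[str, ...] = ("psipred", "jnet", "transec", "proteus")

    def validate(self, require_labels: bool = False) -> None:
        """Check that every chain has a PSSM, all SS sources and (optionally) labels."""
        for chain in self.chains:
            cid = chain.chain_id
            if cid not in self.pssms:
                raise FormatError(f"chain {cid!r}: missing PSSM")
            if self.pssms[cid].raw.shape[0] != chain.length:
                raise FormatError(f"chain {cid!r}: PSSM row count != sequence length")
            preds = self.ss.get(cid, {})
            for src in self.source_order:
                if src not in preds:
                    raise FormatError(f"chain {cid!r}: missing SS source {src!r}")
                if preds[src].length != chain.length:
                    raise FormatError(
                        f"chain {cid!r}/{src}: SS length != sequence length"
                    )
            if require_labels:
                if cid not in self.labels:
                    raise FormatError(f"chain {cid!r}: missing turn labels")
                if len(self.labels[cid].labels) != chain.length:
                    raise FormatError(f"chain {cid!r}: label length != sequence length")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> List[ProteinChain]:
    """Read protein chains from a FASTA file, in file order.

    Sequences are uppercased.  Empty files, duplicate identifiers and illegal
    residue characters raise :class:`FormatError` naming the record.
    """
    path = Path(path)
    chains: List[ProteinChain] = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FormatError(f"duplicate FASTA record id {record.id!r}")
        seen.add(record.id)
        chains.append(ProteinChain(chain_id=record.id, sequence=str(record.seq)))
    if not chains:
        raise FormatError(f"no FASTA records found in {path}")
    return chains


def write_fasta(path, chains: Sequence[ProteinChain], width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for chain in chains:
            fh.write(f">{chain.chain_id}\n")
            for i in range(0, chain.length, width):
                fh.write(chain.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII profile
# ---------------------------------------------------------------------------


def read_pssm(path, chain: ProteinChain) -> PSSMProfile:
    """Parse the first 20-column log-odds block of a PSI-BLAST ASCII profile.

    The percentage block and trailing statistics, when present, are ignored.
    Residue letters are cross-checked against ``chain.sequence``.
    """
    path = Path(path)
    rows: List[List[float]] = []
    letters: List[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if len(tokens) < 22:
                continue
            try:
                idx = int(tokens[0])
            except ValueError:
                continue  # header / alphabet line
            if tokens[1].upper() not in set(AMINO_ACIDS + "X"):
                continue
            try:
                scores = [float(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise FormatError(
                    f"{path.name} line {lineno}: non-numeric score ({exc})"
                ) from None
            if idx != len(rows) + 1:
                raise FormatError(
                    f"{path.name} line {lineno}: expected residue index "
                    f"{len(rows) + 1}, found {idx}"
                )
            rows.append(scores)
            letters.append(tokens[1].upper())
    if len(rows) != chain.length:
        raise FormatError(
            f"{path.name}: {len(rows)} profile rows but chain "
            f"{chain.chain_id!r} has {chain.length} residues"
        )
    for i, (letter, expected) in enumerate(zip(letters, chain.sequence)):
        if letter != expected:
            raise FormatError(
                f"{path.name}: residue mismatch at position {i + 1}: profile "
                f"has {letter!r}, chain {chain.chain_id!r} has {expected!r}"
            )
    return PSSMProfile(chain_id=chain.chain_id, raw=np.array(rows, dtype=float))


def write_pssm(path, chain: ProteinChain, raw: np.ndarray) -> None:
    """Write an integer log-odds matrix in the PSI-BLAST ASCII profile dialect."""
    raw = np.asarray(raw)
    if raw.shape != (chain.length, 20):
        raise FormatError("raw matrix shape does not match chain length")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "  ".join(PSSM_ALPHABET) + "\n")
        for i, (aa, row) in enumerate(zip(chain.sequence, raw), start=1):
            scores = " ".join(f"{int(round(v)):4d}" for v in row)
            fh.write(f"{i:5d} {aa} {scores}\n")


# ---------------------------------------------------------------------------
# secondary-structure prediction TSV
# ---------------------------------------------------------------------------


def read_ss_predictions(path) -> List[SSPrediction]:
    """Read the columnar SS-prediction file, grouped per (chain, source).

    Expected columns: ``chain_id  source  pos  state  conf`` with a header
    line; positions must be contiguous from 1 to L within each group.
    """
    path = Path(path)
    groups: Dict[Tuple[str, str], Tuple[List[str], List[int]]] = {}
    order: List[Tuple[str, str]] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path.name}: empty file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path.name} line {lineno}: expected 5 columns")
            cid, source, pos_s, state, conf_s = parts
            try:
                pos = int(pos_s)
                conf = int(conf_s)
            except ValueError:
                raise FormatError(
                    f"{path.name} line {lineno}: non-integer position/confidence"
                ) from None
            key = (cid, source)
            if key not in groups:
                groups[key] = ([], [])
                order.append(key)
            states, confs = groups[key]
            if pos != len(states) + 1:
                raise FormatError(
                    f"{path.name} line {lineno}: non-contiguous positions for "
                    f"{cid}/{source} (expected {len(states) + 1}, got {pos})"
                )
            states.append(state)
            confs.append(conf)
    result = []
    for cid, source in order:
        states, confs = groups[(cid, source)]
        result.append(
            SSPrediction(
                chain_id=cid, source=source, states="".join(states), confidence=confs
            )
        )
    return result


def write_ss_predictions(path, predictions: Sequence[SSPrediction]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("chain_id\tsource\tpos\tstate\tconf\n")
        for pred in predictions:
            for i, (st, c) in enumerate(zip(pred.states, pred.confidence), start=1):
                fh.write(f"{pred.chain_id}\t{pred.source}\t{i}\t{st}\t{c}\n")


# ---------------------------------------------------------------------------
# turn labels TSV
# ---------------------------------------------------------------------------


def read_labels(path) -> List[TurnLabels]:
    path = Path(path)
    out: List[TurnLabels] = []
    seen = set()
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path.name}: empty file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path.name} line {lineno}: expected 2 columns")
            cid, labels = parts
            if cid in seen:
                raise FormatError(f"{path.name} line {lineno}: duplicate chain {cid!r}")
            seen.add(cid)
            out.append(TurnLabels(chain_id=cid, labels=labels))
    return out


def write_labels(path, labels: Sequence[TurnLabels]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("chain_id\tlabels\n")
        for lab in labels:
            fh.write(f"{lab.chain_id}\t{lab.labels}\n")


# ---------------------------------------------------------------------------
# predictions TSV
# ---------------------------------------------------------------------------


def write_predictions(path, records: Sequence[PredictionRecord]) -> None:
    """Write per-residue predictions as TSV; probabilities with 6 decimals."""
    for rec in records:
        if not (0.0 <= rec.probability <= 1.0):
            raise FormatError(
                f"{rec.chain_id} pos {rec.position}: probability "
                f"{rec.probability} outside [0, 1]"
            )
        if rec.raw_label not in TURN_ALPHABET or rec.smoothed_label not in TURN_ALPHABET:
            raise FormatError(
                f"{rec.chain_id} pos {rec.position}: labels must be 't' or 'n'"
            )
    path = Path(path)
    with path.open("w") as fh:
        fh.write("chain_id\tpos\tprob\traw\tsmoothed\n")
        for rec in records:
            fh.write(
                f"{rec.chain_id}\t{rec.position}\t{rec.probability:.6f}"
                f"\t{rec.raw_label}\t{rec.smoothed_label}\n"
            )


def read_predictions(path) -> List[PredictionRecord]:
    path = Path(path)
    out: List[PredictionRecord] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path.name}: empty file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path.name} line {lineno}: expected 5 columns")
            cid, pos_s, prob_s, raw, smoothed = parts
            out.append(
                PredictionRecord(
                    chain_id=cid,
                    position=int(pos_s),
                    probability=float(prob_s),
                    raw_label=raw,
                    smoothed_label=smoothed,
                )
            )
    return out
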