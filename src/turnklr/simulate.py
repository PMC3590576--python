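"""Seeded generator of synthetic chains, profiles, SS predictions and labels.

Real benchmark sets for β-turn prediction require X-ray structures, an
iterative PSI-BLAST run against nr and four external secondary-structure
predictors; none of that is reproducible offline.  This module emulates the
*statistical structure* those inputs carry so every pipeline stage is
testable:

* labels follow a two-state renewal process — turn segments of length
  ``min_run + Geometric``, separated by geometric non-turn gaps calibrated
  so the expected turn prevalence matches ``turn_fraction`` (≈25% of
  residues sit in turns; runs are never shorter than 4);
* PSSM rows carry a class signal in log-odds space: the first
  ``n_signal_cols`` columns are shifted by ±δ/2 for turn/non-turn residues
  before rounding to integer log-odds (real profiles are integer-valued);
* each residue has a latent 3-state secondary structure (C for turns, a
  helix/strand/coil mix elsewhere); each of the four sources independently
  reports the latent state with probability ``ss_accuracy`` and a higher
  confidence digit when its report is correct.

Everything is reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .formats import (
    AMINO_ACIDS,
    Dataset,
    PSSMProfile,
    ProteinChain,
    SSPrediction,
    TurnLabels,
    write_fasta,
    write_labels,
    write_pssm,
    write_ss_predictions,
)

#: Latent background 3-state mix for non-turn residues (H, E, C).
BACKGROUND_SS = {"H": 0.40, "E": 0.30, "C": 0.30}


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    ``pssm_effect`` δ is the mean log-odds shift between turn and non-turn
    residues on the signal columns; ``ss_accuracy`` is each predictor's
    per-residue probability of reporting the latent state.
    """

    n_chains: int = 100
    length_range: Tuple[int, int] = (40, 100)
    turn_fraction: float = 0.25
    min_run: int = 4
    pssm_effect: float = 1.0
    n_signal_cols: int = 8
    ss_accuracy: float = 0.85
    confidence_fidelity: float = 0.8
    seed: int = 0
    sources: Tuple[str, ...] = ("psipred", "jnet", "transec", "proteus")

    def __post_init__(self) -> None:
        if not (0.0 < self.turn_fraction < 1.0):
            raise ValueError("turn_fraction must lie in (0, 1)")
        if self.min_run < 1:
            raise ValueError("min_run must be at least 1")
        if not (0.0 < self.ss_accuracy <= 1.0):
            raise ValueError("ss_accuracy must lie in (0, 1]")
        if not (0 <= self.n_signal_cols <= 20):
            raise ValueError("n_signal_cols must lie in 0..20")
        # mean turn run = min_run + 1 (geometric tail with p = 0.5); the mean
        # non-turn gap implied by the target prevalence must be at least 1
        mean_turn = self.min_run + 1.0
        mean_gap = mean_turn * (1.0 - self.turn_fraction) / self.turn_fraction
        if mean_gap < 1.0:
            raise ValueError(
                f"turn_fraction {self.turn_fraction} infeasible with "
                f"min_run {self.min_run}"
            )


def _renewal_labels(L: int, cfg: SimConfig, rng: np.random.Generator) -> str:
    """Alternating turn/gap segments; turn runs never truncated below min_run."""
    mean_turn = cfg.min_run + 1.0
    mean_gap = mean_turn * (1.0 - cfg.turn_fraction) / cfg.turn_fraction
    p_gap = min(1.0, 1.0 / mean_gap)
    out: List[str] = []
    in_turn = bool(rng.random() < cfg.turn_fraction)
    while len(out) < L:
        remaining = L - len(out)
        if in_turn:
            run = cfg.min_run + int(rng.geometric(0.5)) - 1
            if remaining < cfg.min_run:
                out.extend("n" * remaining)  # never emit a short interior run
            else:
                out.extend("t" * min(run, remaining))
        else:
            gap = int(rng.geometric(p_gap))
            out.extend("n" * min(gap, remaining))
        in_turn = not in_turn
    return "".join(out[:L])


def _pssm_rows(
    is_turn: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    L = len(is_turn)
    raw = rng.normal(0.0, 1.0, size=(L, 20))
    shift = np.where(is_turn, +cfg.pssm_effect / 2.0, -cfg.pssm_effect / 2.0)
    raw[:, : cfg.n_signal_cols] += shift[:, None]
    return np.round(raw)  # integer log-odds, as real profiles carry


def _latent_ss(is_turn: np.ndarray, rng: np.random.Generator) -> List[str]:
    states = list(BACKGROUND_SS)
    probs = np.array([BACKGROUND_SS[s] for s in states])
    latent = []
    for turn in is_turn:
        if turn:
            latent.append("C")
        else:
            latent.append(states[int(rng.choice(len(states), p=probs))])
    return latent


def _emit_source(
    latent: List[str], cfg: SimConfig, rng: np.random.Generator
) -> Tuple[str, List[int]]:
    states = []
    confs = []
    for true_state in latent:
        if rng.random() < cfg.ss_accuracy:
            emitted = true_state
        else:
            others = [s for s in "HEC" if s != true_state]
            emitted = others[int(rng.integers(2))]
        match = emitted == true_state
        if rng.random() < cfg.confidence_fidelity:
            center = 7.0 if match else 3.0
            conf = int(np.clip(round(rng.normal(center, 1.5)), 0, 9))
        else:
            conf = int(rng.integers(0, 10))
        states.append(emitted)
        confs.append(conf)
    return "".join(states), confs


def generate_dataset(config: SimConfig) -> Dataset:
    """Generate a fully annotated synthetic dataset from the configuration."""
    rng = np.random.default_rng(config.seed)
    chains: List[ProteinChain] = []
    pssms: Dict[str, PSSMProfile] = {}
    ss: Dict[str, Dict[str, SSPrediction]] = {}
    labels: Dict[str, TurnLabels] = {}

    lo, hi = config.length_range
    for c in range(config.n_chains):
        cid = f"syn{c + 1:04d}"
        L = int(rng.integers(lo, hi + 1))
        sequence = "".join(
            AMINO_ACIDS[int(i)] for i in rng.integers(0, 20, size=L)
        )
        chain = ProteinChain(chain_id=cid, sequence=sequence)
        lab = _renewal_labels(L, config, rng)
        is_turn = np.array([ch == "t" for ch in lab])
        raw = _pssm_rows(is_turn, config, rng)
        latent = _latent_ss(is_turn, rng)
        per_source: Dict[str, SSPrediction] = {}
        for src in config.sources:
            states, confs = _emit_source(latent, config, rng)
            per_source[src] = SSPrediction(
                chain_id=cid, source=src, states=states, confidence=confs
            )
        chains.append(chain)
        pssms[cid] = PSSMProfile(chain_id=cid, raw=raw)
        ss[cid] = per_source
        labels[cid] = TurnLabels(chain_id=cid, labels=lab)

    return Dataset(
        chains=chains,
        pssms=pssms,
        ss=ss,
        labels=labels,
        source_order=config.sources,
    )


def write_fixture_files(dataset: Dataset, outdir) -> List[Path]:
    """Write the dataset in every supported on-disk format.

    Produces ``chains.fasta``, one ``<chain_id>.pssm`` per chain,
    ``ss_predictions.tsv`` and ``labels.tsv``; all are readable back by
    :mod:`turnklr.formats` with round-trip identity.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    fasta = outdir / "chains.fasta"
    write_fasta(fasta, dataset.chains)
    written.append(fasta)

    for chain in dataset.chains:
        p = outdir / f"{chain.chain_id}.pssm"
        write_pssm(p, chain, dataset.pssms[chain.chain_id].raw)
        written.append(p)

    ss_path = outdir / "ss_predictions.tsv"
    preds = [
        dataset.ss[chain.chain_id][src]
        for chain in dataset.chains
        for src in dataset.source_order
    ]
    write_ss_predictions(ss_path, preds)
    written.append(ss_path)

    labels_path = outdir / "labels.tsv"
    write_labels(labels_path, [dataset.labels[c.chain_id] for c in dataset.chains])
    written.append(labels_path)
    return written
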