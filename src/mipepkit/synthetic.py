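"""Seeded synthetic datasets with the statistical structure of IP-MS studies.

Three generators cover the data the downstream stages consume:

* :func:`generate_apms` — replicated bait vs. control immunoprecipitation
  intensity tables (default n = 3 bait, n = 4 control replicates) with planted
  enriched preys, intensity-dependent (missing-not-at-random) dropout, and
  spectral counts coupled to intensity.
* :func:`generate_proteome` — two-condition whole-proteome intensity matrices
  with planted differential proteins.
* :func:`generate_sequences` — random amino-acid sequences with motif literals
  planted at known 1-based coordinates.

Every generator records its ground truth in a :class:`SyntheticTruth` so that
recovery by the calling/filtering/scanning stages can be measured exactly.

Randomness: one seed per call; each protein (or sequence) draws from its own
sub-stream derived via ``numpy.random.SeedSequence(seed, spawn_key=...)``, so
enlarging a dataset never perturbs rows already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ProteinQuantTable, SeqEntry

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class APMSSimConfig:
    """Parameters of the simulated affinity-purification MS experiment.

    Intensities live on the log2 scale: a background prey draws a protein-level
    baseline from N(``background_log2_mean``, ``background_log2_sd``), each
    replicate adds N(0, ``replicate_log2_sd``) measurement noise, and planted
    interactors gain ``enrichment_log2`` in bait samples only. Detection is
    missing-not-at-random: a cell is observed with probability
    ``logistic(dropout_slope * (log2 intensity − dropout_midpoint_log2))``;
    ``dropout_midpoint_log2 = None`` disables dropout. Spectral counts are
    Poisson with mean ``sc_per_log2 · 2^(log2 intensity − background_log2_mean)``
    and are forced to 0 wherever the intensity is unobserved.
    """

    n_proteins: int = 500
    n_bait_reps: int = 3
    n_ctrl_reps: int = 4
    n_true_interactors: int = 20
    enrichment_log2: float = 8.0
    background_log2_mean: float = 25.0
    background_log2_sd: float = 1.5
    replicate_log2_sd: float = 0.25
    dropout_midpoint_log2: float | None = None
    dropout_slope: float = 1.0
    sc_per_log2: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_bait_reps", "n_ctrl_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_true_interactors < 0:
            raise ValueError("n_true_interactors must be >= 0")
        if self.n_true_interactors > self.n_proteins:
            raise ValueError("n_true_interactors cannot exceed n_proteins")
        for name in ("background_log2_sd", "replicate_log2_sd", "dropout_slope", "sc_per_log2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic dataset.

    ``interactor_ids`` holds the planted enriched/differential protein ids,
    ``effect_log2_by_id`` their planted log2 effects, and ``motif_placements``
    the planted motifs as ``(sequence id, motif class id, start, end)`` with
    1-based inclusive coordinates.
    """

    interactor_ids: set[str] = field(default_factory=set)
    effect_log2_by_id: dict[str, float] = field(default_factory=dict)
    motif_placements: list[tuple[str, str, int, int]] = field(default_factory=list)


def _protein_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_apms(
    config: APMSSimConfig,
    effects_log2: Mapping[str, float] | None = None,
) -> tuple[ProteinQuantTable, SyntheticTruth]:
    """Simulate a bait vs. control IP quantification table.

    The first ``n_true_interactors`` proteins are the planted interactors.
    ``effects_log2`` optionally overrides the planted bait-side log2 effect per
    protein id (used e.g. to simulate a motif-mutant bait in which a subset of
    interactors loses enrichment); ids absent from the mapping keep the default
    behaviour.
    """
    ids = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    planted = set(ids[: config.n_true_interactors])
    effects = {pid: config.enrichment_log2 for pid in planted}
    if effects_log2:
        unknown = set(effects_log2) - set(ids)
        if unknown:
            raise ValueError(f"effect override for unknown protein ids: {sorted(unknown)}")
        effects.update(effects_log2)

    n_bait, n_ctrl = config.n_bait_reps, config.n_ctrl_reps
    bait_cols = [f"bait_{r + 1}" for r in range(n_bait)]
    ctrl_cols = [f"control_{r + 1}" for r in range(n_ctrl)]
    cols = bait_cols + ctrl_cols
    samples = pd.DataFrame(
        {
            "condition": ["bait"] * n_bait + ["control"] * n_ctrl,
            "replicate": list(range(1, n_bait + 1)) + list(range(1, n_ctrl + 1)),
        },
        index=pd.Index(cols, name="sample"),
    )

    intens = np.empty((config.n_proteins, n_bait + n_ctrl))
    counts = np.zeros_like(intens, dtype=int)
    for i, pid in enumerate(ids):
        rng = _protein_rng(config.seed, i)
        baseline = config.background_log2_mean + config.background_log2_sd * rng.standard_normal()
        log2 = baseline + config.replicate_log2_sd * rng.standard_normal(n_bait + n_ctrl)
        log2[:n_bait] += effects.get(pid, 0.0)
        if config.dropout_midpoint_log2 is None:
            observed = np.ones(log2.shape, dtype=bool)
        else:
            p_obs = 1.0 / (
                1.0 + np.exp(-config.dropout_slope * (log2 - config.dropout_midpoint_log2))
            )
            observed = rng.random(log2.shape) < p_obs
        lam = config.sc_per_log2 * np.exp2(log2 - config.background_log2_mean)
        counts[i] = np.where(observed, rng.poisson(lam), 0)
        intens[i] = np.where(observed, np.exp2(log2), np.nan)

    imat = pd.DataFrame(intens, index=pd.Index(ids, name="protein_id"), columns=cols)
    sc = pd.DataFrame(counts, index=imat.index, columns=cols)
    table = ProteinQuantTable(imat, samples, sc, source="generate_apms")
    truth = SyntheticTruth(
        interactor_ids=set(planted),
        effect_log2_by_id={pid: effects[pid] for pid in planted},
    )
    return table, truth


def generate_proteome(
    n_proteins: int,
    n_reps_per_condition: int = 3,
    n_diff: int = 0,
    diff_log2: float = 0.0,
    sd: float = 0.5,
    background_log2_mean: float = 25.0,
    background_log2_sd: float = 1.5,
    seed: int = 0,
) -> tuple[ProteinQuantTable, SyntheticTruth]:
    """Simulate a two-condition whole-proteome intensity matrix.

    Each protein draws a shared baseline; replicate cells add N(0, ``sd``)
    noise on the log2 scale. The first ``n_diff`` proteins are shifted by
    ``diff_log2`` in condition B only. No missingness is simulated (the DIA
    regime: near-complete quantification).
    """
    if n_proteins <= 0 or n_reps_per_condition < 2:
        raise ValueError("need n_proteins > 0 and >= 2 replicates per condition")
    if n_diff < 0 or n_diff > n_proteins:
        raise ValueError("n_diff must lie in [0, n_proteins]")
    if sd <= 0 or background_log2_sd <= 0:
        raise ValueError("standard deviations must be > 0")

    ids = [f"P{i + 1:05d}" for i in range(n_proteins)]
    planted = set(ids[:n_diff])
    n = n_reps_per_condition
    cols = [f"conditionA_{r + 1}" for r in range(n)] + [f"conditionB_{r + 1}" for r in range(n)]
    samples = pd.DataFrame(
        {
            "condition": ["conditionA"] * n + ["conditionB"] * n,
            "replicate": list(range(1, n + 1)) * 2,
        },
        index=pd.Index(cols, name="sample"),
    )
    intens = np.empty((n_proteins, 2 * n))
    for i, pid in enumerate(ids):
        rng = _protein_rng(seed, i)
        baseline = background_log2_mean + background_log2_sd * rng.standard_normal()
        log2 = baseline + sd * rng.standard_normal(2 * n)
        if pid in planted:
            log2[n:] += diff_log2
        intens[i] = np.exp2(log2)
    imat = pd.DataFrame(intens, index=pd.Index(ids, name="protein_id"), columns=cols)
    table = ProteinQuantTable(imat, samples, None, source="generate_proteome")
    truth = SyntheticTruth(
        interactor_ids=set(planted),
        effect_log2_by_id={pid: diff_log2 for pid in planted},
    )
    return table, truth


def generate_sequences(
    n_seqs: int,
    length: int,
    plant: Sequence[tuple] = (),
    seed: int = 0,
) -> tuple[list[SeqEntry], SyntheticTruth]:
    """Generate random amino-acid sequences with motif literals planted.

    Each ``plant`` entry is ``(literal, start)`` with a 1-based inclusive start
    (optionally ``(literal, start, seq_index)`` with a 0-based sequence index;
    by default plant *j* goes into sequence *j*). The literal overwrites the
    residues at ``start .. start+len(literal)-1`` and must fit within
    ``length``; out-of-bounds placements raise ``ValueError``.
    """
    if n_seqs <= 0 or length <= 0:
        raise ValueError("n_seqs and length must be positive")
    records: list[SeqEntry] = []
    seqs: list[np.ndarray] = []
    for i in range(n_seqs):
        rng = _protein_rng(seed, i)
        seqs.append(rng.choice(_AA20, size=length))

    truth = SyntheticTruth()
    for j, entry in enumerate(plant):
        if len(entry) == 2:
            literal, start = entry
            idx = j
        else:
            literal, start, idx = entry
        if not 0 <= idx < n_seqs:
            raise ValueError(f"plant {j}: sequence index {idx} out of range")
        end = start + len(literal) - 1
        if start < 1 or end > length:
            raise ValueError(
                f"plant {j}: literal {literal!r} at start {start} does not fit in length {length}"
            )
        seqs[idx][start - 1 : end] = list(literal.upper())
        truth.motif_placements.append((f"S{idx + 1:04d}", literal.upper(), start, end))

    for i, arr in enumerate(seqs):
        records.append(SeqEntry(f"S{i + 1:04d}", "".join(arr)))
    return records, truth
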