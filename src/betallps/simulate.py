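"""Synthetic energy tables, labeled sequence sets, and planted-score
feature datasets.

These generators let the whole pipeline (scan -> features -> training ->
evaluation) run end to end with no external downloads.  They are
statistical stand-ins: sequences are polar backgrounds with short planted
hydrophobic stretches, echoing the phenomenology of phase-separating
sequences whose best beta-pairing is a short (4-8 residue) V/I/L/F-rich
stretch flanked by charged/polar residues; they do not emulate real
proteome composition or disorder content.  All generators are
bitwise-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import composite_score
from .io import SequenceRecord
from .pairing import AMINO_ACIDS, EnergyTable, Orientation

#: Kyte-Doolittle hydropathy (J. Mol. Biol. 157:105, 1982), the
#: hydrophobicity-like vector behind the "hydrophobic" table style.
#: V, I, L, F rank highest after rescaling to [0, 1].
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: rescaled to [0, 1]: h = (KD + 4.5) / 9
HYDROPHOBICITY = {a: (v + 4.5) / 9.0 for a, v in KYTE_DOOLITTLE.items()}

#: offset making typical polar-polar pairs mildly destabilizing while
#: hydrophobic-hydrophobic pairs stay net-attractive
HYDRO_TABLE_OFFSET = 0.3
#: antiparallel pairings are scaled down relative to parallel ones
ANTIPARALLEL_FACTOR = 0.9

#: polar-enriched background composition (probabilities sum to 1); the
#: strongly hydrophobic letters V, I, L, F, C, M are kept rare so planted
#: stretches dominate the pairing scan
BACKGROUND_FREQS = {
    "S": 0.10, "T": 0.08, "N": 0.06, "Q": 0.07, "G": 0.10,
    "P": 0.07, "D": 0.07, "E": 0.09, "K": 0.08, "R": 0.07,
    "H": 0.03, "A": 0.05, "Y": 0.02, "W": 0.01, "C": 0.01,
    "M": 0.01, "F": 0.01, "L": 0.03, "I": 0.02, "V": 0.02,
}


def generate_energy_tables(
    seed: int = 0, style: str = "hydrophobic"
) -> tuple[EnergyTable, EnergyTable]:
    """Parallel and antiparallel 20x20 energy tables for testing.

    Styles: ``zero`` (all zeros), ``hydrophobic``
    (``e(a, b) = offset - h(a) h(b)`` with the rescaled Kyte-Doolittle
    vector, antiparallel scaled by ``ANTIPARALLEL_FACTOR``), and
    ``random`` (i.i.d. normal entries, sd 0.5).
    """
    if style == "zero":
        return (
            EnergyTable.zeros(Orientation.PARALLEL),
            EnergyTable.zeros(Orientation.ANTIPARALLEL),
        )
    if style == "hydrophobic":
        h = np.array([HYDROPHOBICITY[a] for a in AMINO_ACIDS])
        par = HYDRO_TABLE_OFFSET - np.outer(h, h)
        anti = ANTIPARALLEL_FACTOR * par
        return (
            EnergyTable(Orientation.PARALLEL, par),
            EnergyTable(Orientation.ANTIPARALLEL, anti),
        )
    if style == "random":
        rng = np.random.default_rng(seed)
        return (
            EnergyTable(Orientation.PARALLEL, rng.normal(0.0, 0.5, (20, 20))),
            EnergyTable(Orientation.ANTIPARALLEL, rng.normal(0.0, 0.5, (20, 20))),
        )
    raise ValueError(f"unknown table style {style!r}")


@dataclasses.dataclass
class SequenceGenConfig:
    """Settings for the labeled synthetic sequence generator.

    Lengths default to 160-260 residues so every regular record passes the
    length-140 compatibility filter; ``n_short`` and ``n_nonstandard``
    optionally add records that the filter must drop.
    """

    n_pos: int = 50
    n_neg: int = 50
    length_range: tuple[int, int] = (160, 260)
    stretch_len_range: tuple[int, int] = (4, 8)
    stretch_alphabet: str = "VILF"
    center_stretch: bool = False
    n_short: int = 0
    n_nonstandard: int = 0
    background_freqs: dict = dataclasses.field(
        default_factory=lambda: dict(BACKGROUND_FREQS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ValueError("invalid length range")
        if self.stretch_len_range[0] > self.stretch_len_range[1]:
            raise ValueError("invalid stretch length range")
        if self.stretch_len_range[1] > self.length_range[0]:
            raise ValueError("planted stretch cannot exceed the shortest sequence")
        total = sum(self.background_freqs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"background frequencies sum to {total}, expected 1")


def _random_background(rng, length, letters, probs) -> np.ndarray:
    return rng.choice(letters, size=length, p=probs)


def generate_sequences(cfg: SequenceGenConfig):
    """Labeled FASTA-style records with planted hydrophobic stretches.

    Positives carry one contiguous stretch drawn from ``stretch_alphabet``
    (length uniform in ``stretch_len_range``) at a recorded position;
    negatives are pure background.  Returns ``(records, truth)`` where
    ``truth`` has columns id, label, planted_k, planted_l, valid, reason
    (1-based inclusive stretch coordinates; planted columns are <NA> for
    negatives and filter-exercise records).
    """
    rng = np.random.default_rng(cfg.seed)
    letters = np.array(sorted(cfg.background_freqs))
    probs = np.array([cfg.background_freqs[a] for a in letters])
    probs = probs / probs.sum()
    records: list[SequenceRecord] = []
    rows = []

    for i in range(cfg.n_pos):
        n = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq = _random_background(rng, n, letters, probs)
        slen = int(rng.integers(cfg.stretch_len_range[0], cfg.stretch_len_range[1] + 1))
        if cfg.center_stretch:
            k0 = (n - slen) // 2
        else:
            k0 = int(rng.integers(0, n - slen + 1))
        stretch = rng.choice(list(cfg.stretch_alphabet), size=slen)
        seq[k0 : k0 + slen] = stretch
        rid = f"pos_{i:04d}"
        records.append(SequenceRecord(rid, "synthetic positive", "".join(seq)))
        rows.append(
            dict(id=rid, label=1, planted_k=k0 + 1, planted_l=k0 + slen,
                 valid=True, reason="")
        )

    for i in range(cfg.n_neg):
        n = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq = _random_background(rng, n, letters, probs)
        rid = f"neg_{i:04d}"
        records.append(SequenceRecord(rid, "synthetic negative", "".join(seq)))
        rows.append(
            dict(id=rid, label=0, planted_k=pd.NA, planted_l=pd.NA,
                 valid=True, reason="")
        )

    for i in range(cfg.n_short):
        n = int(rng.integers(20, 140))  # below the length-140 filter
        seq = _random_background(rng, n, letters, probs)
        rid = f"short_{i:04d}"
        records.append(SequenceRecord(rid, "synthetic short", "".join(seq)))
        rows.append(
            dict(id=rid, label=0, planted_k=pd.NA, planted_l=pd.NA,
                 valid=False, reason="too_short")
        )

    for i in range(cfg.n_nonstandard):
        n = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq = _random_background(rng, n, letters, probs)
        pos = rng.integers(0, n, size=max(1, n // 100))
        seq[pos] = rng.choice(list("XUBZ"), size=pos.size)
        rid = f"odd_{i:04d}"
        records.append(SequenceRecord(rid, "synthetic nonstandard letters", "".join(seq)))
        rows.append(
            dict(id=rid, label=0, planted_k=pd.NA, planted_l=pd.NA,
                 valid=False, reason="nonstandard_letter")
        )

    truth = pd.DataFrame(
        rows, columns=["id", "label", "planted_k", "planted_l", "valid", "reason"]
    )
    return records, truth


def synthetic_pscores(ids: Sequence[str], seed: int = 0, sd: float = 1.0) -> pd.Series:
    """Label-independent stand-in P values (pure seeded noise).

    NOT the published pi-pi score: used when the study design requires a P
    column carrying no signal, e.g. to test that pairing-derived terms add
    discriminative power on their own.
    """
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(0.0, sd, size=len(ids)), index=list(ids), name="P")


#: residues able to contribute planar pi contacts (aromatics plus
#: sp2-containing side chains and the backbone-exposing G/P)
_PI_LETTERS = set("FWYHQNRDEGP")


def pi_contact_stub(sequence: str) -> float:
    """Crude pi-contact frequency: fraction of pi-capable residues.

    A deliberately simple, clearly-labeled stand-in for an external pi-pi
    score, for synthetic tests only.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return sum(1 for a in sequence if a in _PI_LETTERS) / len(sequence)


@dataclasses.dataclass
class PlantedScoreConfig:
    """Settings for the planted linear-score feature generator.

    ``weights`` are the true (alpha*, beta*, gamma*) of the planted s4;
    labels are Bernoulli(logistic((s4* - median s4*) / temperature)), the
    median centering keeping both classes populated.
    """

    weights: tuple[float, float, float] = (86.0, -0.56, -1.40)
    n: int = 2000
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.weights)):
            raise ValueError("planted weights must be finite")
        if self.n < 4:
            raise ValueError("need at least 2 samples per class")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


def generate_feature_dataset(cfg: PlantedScoreConfig):
    """Feature table plus labels from a planted s4 with logistic noise.

    Feature distributions (per sequence): chain length N uniform in
    [140, 1000]; energy density E/N = -Gamma(shape 4, scale 0.01)
    (mean -0.04); register shift S ~ Exp(1.5); pairing length lp uniform
    in {4..12}; P ~ Normal(0, 2).  Returns ``(features, labels)``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    N = rng.integers(140, 1001, size=n)
    e_over_n = -rng.gamma(4.0, 0.01, size=n)
    S = rng.exponential(1.5, size=n)
    lp = rng.integers(4, 13, size=n)
    P = rng.normal(0.0, 2.0, size=n)
    features = pd.DataFrame(
        {
            "id": [f"sim_{i:05d}" for i in range(n)],
            "N": N,
            "E": e_over_n * N,
            "lp": lp,
            "S": S,
            "P": P,
            "E_over_N": e_over_n,
            "lnS1": np.log(S + 1.0),
            "lnlp": np.log(lp),
            "f": np.full(n, np.nan),
        }
    )
    alpha, beta, gamma = cfg.weights
    planted = composite_score(
        "s4", features, {"E_over_N": alpha, "lnS1": beta, "lnlp": gamma}
    )
    centered = planted - np.median(planted)
    if cfg.temperature == 0:
        prob = (centered > 0).astype(float)
    else:
        prob = expit(centered / cfg.temperature)
    labels = pd.Series((rng.uniform(size=n) < prob).astype(int), name="label")
    return features, labels


def planted_score(features: pd.DataFrame, cfg: PlantedScoreConfig) -> np.ndarray:
    """Evaluate the planted s4 scorer on a feature table."""
    alpha, beta, gamma = cfg.weights
    return composite_score(
        "s4", features, {"E_over_N": alpha, "lnS1": beta, "lnlp": gamma}
    )
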