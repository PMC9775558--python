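"""Per-sequence features and the composite LLPS scoring functions.

Six linear scoring functions combine the pairing-scan features with an
externally supplied pi-pi score ``P``:

.. code-block:: text

    s0  = E/N + b*ln(S+1)
    s00 = E/N + b*ln(S+1) + g*ln(lp)
    s1  = a*E/N + P
    s2  = b*ln(S+1) + P
    s3  = a*E/N + b*ln(S+1) + P
    s4  = a*E/N + b*ln(S+1) + g*ln(lp) + P

Higher score means "predicted phase-separating".  ``E/N`` is the best
pairing energy per residue (a mean-field energy density), and the
logarithmic transforms of the register shift ``S`` and pairing length
``lp`` connect those chain-geometry counts to conformational entropies.
``f`` is the fractional position of the best-pairing stretch along the
chain, in (0, 1/2], with f = 1/2 at the chain center.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pairing import PairingSummary

#: free weights and the fixed (unit-coefficient) term of each score
SCORE_TERMS: dict[str, tuple[tuple[str, ...], str]] = {
    "s0": (("lnS1",), "E_over_N"),
    "s00": (("lnS1", "lnlp"), "E_over_N"),
    "s1": (("E_over_N",), "P"),
    "s2": (("lnS1",), "P"),
    "s3": (("E_over_N", "lnS1"), "P"),
    "s4": (("E_over_N", "lnS1", "lnlp"), "P"),
}

SCORE_NAMES = tuple(SCORE_TERMS)

#: conventional weight symbols, for table/report headers
WEIGHT_SYMBOLS = {"E_over_N": "alpha", "lnS1": "beta", "lnlp": "gamma"}

FEATURE_COLUMNS = ["id", "N", "E", "lp", "S", "P", "E_over_N", "lnS1", "lnlp", "f"]


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """Assembled predictors for one sequence."""

    id: str
    N: int
    E: float
    lp: int
    S: float
    P: float
    E_over_N: float = dataclasses.field(init=False)
    lnS1: float = dataclasses.field(init=False)
    lnlp: float = dataclasses.field(init=False)
    f: float | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"chain length must be >= 1, got {self.N}")
        if self.lp < 1:
            raise ValueError(f"pairing length must be >= 1, got {self.lp}")
        if self.S < 0:
            raise ValueError(f"register shift must be >= 0, got {self.S}")
        if not math.isfinite(self.P):
            raise ValueError("PScore must be finite")
        object.__setattr__(self, "E_over_N", self.E / self.N)
        object.__setattr__(self, "lnS1", math.log(self.S + 1.0))
        object.__setattr__(self, "lnlp", math.log(self.lp))

    def as_dict(self) -> dict[str, float]:
        d = dataclasses.asdict(self)
        return d


def compute_features(summary: PairingSummary, pscore: float) -> FeatureVector:
    """Assemble the feature vector from a pairing summary and an external P.

    The fractional position ``f`` is computed from the best pairing's first
    stretch (1-based inclusive coordinates).
    """
    return FeatureVector(
        id=summary.id,
        N=summary.N,
        E=summary.E,
        lp=summary.lp,
        S=summary.S,
        P=float(pscore),
        f=fractional_position(summary.best.k, summary.best.l, summary.N),
    )


def fractional_position(m: int, n: int, N: int) -> float:
    """Fractional position f = min((m+n)/2N, 1 - (m+n)/2N) of a stretch.

    ``m``/``n`` are the 1-based inclusive first/last residue of the stretch
    and ``N`` the chain length; f lies in (0, 1/2], reaching 1/2 when the
    stretch midpoint sits at the chain center.
    """
    if not (1 <= m <= n <= N):
        raise ValueError(f"invalid stretch ({m}, {n}) for chain of length {N}")
    x = (m + n) / (2.0 * N)
    return min(x, 1.0 - x)


def composite_score(
    name: str,
    fv: "FeatureVector | Mapping[str, float] | pd.DataFrame",
    weights: Mapping[str, float],
):
    """Evaluate one of the composite scores s0..s4.

    ``weights`` maps feature names (``E_over_N``, ``lnS1``, ``lnlp``) to
    coefficients; exactly the free weights of the named score must be
    present.  Accepts a single feature vector/mapping or a feature table.
    """
    if name not in SCORE_TERMS:
        raise KeyError(f"unknown score {name!r}; expected one of {SCORE_NAMES}")
    free, fixed = SCORE_TERMS[name]
    missing = [t for t in free if t not in weights]
    if missing:
        raise KeyError(f"score {name} requires weights for {missing}")
    extra = [t for t in weights if t not in free]
    if extra:
        raise KeyError(f"score {name} does not use weights {extra}")
    if isinstance(fv, FeatureVector):
        fv = fv.as_dict()
    if isinstance(fv, pd.DataFrame):
        total = fv[fixed].to_numpy(dtype=float).copy()
        for term in free:
            total += weights[term] * fv[term].to_numpy(dtype=float)
        return total
    total = float(fv[fixed])
    for term in free:
        total += weights[term] * float(fv[term])
    return total


def score_table(
    features: pd.DataFrame, weights_by_score: Mapping[str, Mapping[str, float]]
) -> pd.DataFrame:
    """Score table (one column per score name) for a feature table."""
    out = pd.DataFrame({"id": features["id"]})
    for name, w in weights_by_score.items():
        out[name] = composite_score(name, features, w)
    return out


def features_from_scan(
    scan: pd.DataFrame, pscores: Mapping[str, float] | pd.Series
) -> pd.DataFrame:
    """Join a batch-scan table with per-sequence P values.

    Sequences with no P value (e.g. removed by the compatibility filter of
    the external pi-pi scorer) are excluded, never imputed.
    """
    pscores = pd.Series(dict(pscores), name="P") if not isinstance(pscores, pd.Series) else pscores
    df = scan.merge(pscores.rename("P"), left_on="id", right_index=True, how="inner")
    df["E_over_N"] = df["E"] / df["N"]
    df["lnS1"] = np.log(df["S"] + 1.0)
    df["lnlp"] = np.log(df["lp"])
    df["f"] = [
        fractional_position(int(k), int(l), int(n))
        for k, l, n in zip(df["best_k"], df["best_l"], df["N"])
    ]
    return df[FEATURE_COLUMNS].reset_index(drop=True)


def compare_positional_sets(
    fA: Sequence[float], fB: Sequence[float]
) -> tuple[tuple[float, float], tuple[float, float], float]:
    """Two-sample comparison of fractional-position sets.

    Returns ``((meanA, semA), (meanB, semB), Z)`` with the standard
    two-sample statistic Z = (meanA - meanB) / sqrt(semA^2 + semB^2).
    """
    a = np.asarray(fA, dtype=float)
    b = np.asarray(fB, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each set needs at least 2 values for a standard error")
    sem_a = float(np.std(a, ddof=1) / math.sqrt(a.size))
    sem_b = float(np.std(b, ddof=1) / math.sqrt(b.size))
    denom = math.hypot(sem_a, sem_b)
    if denom == 0.0:
        raise ValueError("both sets have zero variance; Z undefined")
    z = (float(np.mean(a)) - float(np.mean(b))) / denom
    return (float(np.mean(a)), sem_a), (float(np.mean(b)), sem_b), z
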