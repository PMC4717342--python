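"""Four-state Markov chain for vertical transmission of two heritable viral strains.

A matriline of a vertically infected symbiont (here the filamentous virus LbFV
of the parasitoid wasp *Leptopilina boulardi*) can be in one of four infection
states: uninfected, carrying strain 1 only, carrying strain 2 only, or
coinfected.  Under the *independence hypothesis* — each strain is transmitted
from mother to offspring with its own single-infection efficiency, unaffected
by the presence of the other strain — transmission over one generation is a
Markov transition on this state space.

Writing ``P1`` and ``P2`` for the single-infection vertical transmission
efficiencies of strain 1 and strain 2, the row-stochastic transition matrix
(mother state in rows, offspring state in columns, canonical order
uninfected / strain1 / strain2 / coinfected) is::

    M = [ 1                   0             0             0       ]
        [ 1 - P1              P1            0             0       ]
        [ 1 - P2              0             P2            0       ]
        [ (1 - P1)(1 - P2)    P1(1 - P2)    (1 - P1)P2    P1 P2   ]

The uninfected state is absorbing, and a mother can never transmit a strain
she does not carry (the structural zeros above the diagonal blocks).  State
distributions ``G_n`` propagate as ``G_{n+1} = G_n · M``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InfectionStatus",
    "STATUSES",
    "STATUS_LABELS",
    "StrainParams",
    "TransitionMatrix",
    "StateDistribution",
    "build_transition_matrix",
    "propagate",
    "retention_closed_form",
]


class InfectionStatus(enum.IntEnum):
    """Infection status of an individual (or matriline) with respect to two strains.

    The integer values fix the canonical ordering used by every vector and
    matrix in the package.
    """

    UNINFECTED = 0
    STRAIN1 = 1
    STRAIN2 = 2
    COINFECTED = 3

    @property
    def carries_strain1(self) -> bool:
        return self in (InfectionStatus.STRAIN1, InfectionStatus.COINFECTED)

    @property
    def carries_strain2(self) -> bool:
        return self in (InfectionStatus.STRAIN2, InfectionStatus.COINFECTED)

    def carries(self, strain: int) -> bool:
        """Whether this status includes strain 1 or strain 2."""
        if strain not in (1, 2):
            raise ValueError(f"strain must be 1 or 2, got {strain}")
        return self.carries_strain1 if strain == 1 else self.carries_strain2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "InfectionStatus":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown infection status {label!r}; "
                f"expected one of {', '.join(STATUS_LABELS)}"
            ) from None

    @classmethod
    def from_carriage(cls, strain1: bool, strain2: bool) -> "InfectionStatus":
        return cls(int(bool(strain1)) + 2 * int(bool(strain2)))


STATUSES = tuple(InfectionStatus)
STATUS_LABELS = tuple(s.label for s in STATUSES)


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class StrainParams:
    """Single-infection vertical transmission efficiencies of the two strains.

    ``p1`` and ``p2`` are per-generation mother-to-offspring transmission
    probabilities measured in singly infected lines.
    """

    p1: float
    p2: float
    name1: str = "strain1"
    name2: str = "strain2"

    def __post_init__(self) -> None:
        object.__setattr__(self, "p1", _check_prob(self.p1, "p1"))
        object.__setattr__(self, "p2", _check_prob(self.p2, "p2"))

    def p(self, strain: int) -> float:
        if strain not in (1, 2):
            raise ValueError(f"strain must be 1 or 2, got {strain}")
        return self.p1 if strain == 1 else self.p2

    def to_dict(self) -> dict:
        return {"p1": self.p1, "p2": self.p2, "name1": self.name1, "name2": self.name2}

    @classmethod
    def from_dict(cls, d: dict) -> "StrainParams":
        return cls(
            p1=d["p1"],
            p2=d["p2"],
            name1=d.get("name1", "strain1"),
            name2=d.get("name2", "strain2"),
        )


_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 4x4 transition matrix over infection statuses.

    Rows index the mother's status, columns the offspring's status, both in
    canonical order.  Construction validates row sums (absolute tolerance
    1e-12) and entry ranges.
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"transition matrix must be 4x4, got shape {m.shape}")
        if np.any(m < 0.0) or np.any(m > 1.0):
            raise ValueError("transition matrix entries must lie in [0, 1]")
        row_sums = m.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > _ROW_SUM_TOL):
            raise ValueError(f"transition matrix rows must sum to 1, got {row_sums}")
        m.setflags(write=False)
        object.__setattr__(self, "entries", m)

    def __getitem__(self, key) -> float:
        mother, offspring = key
        return float(self.entries[int(mother), int(offspring)])

    def row(self, mother: InfectionStatus) -> np.ndarray:
        return self.entries[int(mother)]

    def to_json(self, indent: int | None = None) -> str:
        payload = {
            row.label: {
                col.label: float(self.entries[row, col]) for col in STATUSES
            }
            for row in STATUSES
        }
        return json.dumps(payload, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "TransitionMatrix":
        payload = json.loads(text)
        m = np.array(
            [[payload[r.label][c.label] for c in STATUSES] for r in STATUSES],
            dtype=float,
        )
        return cls(m)


@dataclass(frozen=True)
class StateDistribution:
    """Probability vector ``G_n`` over the four infection statuses at generation ``n``."""

    probs: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.probs, dtype=float)
        if v.shape != (4,):
            raise ValueError(f"state distribution must have length 4, got shape {v.shape}")
        if np.any(v < 0.0) or np.any(v > 1.0):
            raise ValueError("state probabilities must lie in [0, 1]")
        if abs(v.sum() - 1.0) > _ROW_SUM_TOL:
            raise ValueError(f"state probabilities must sum to 1, got {v.sum()!r}")
        gen = int(self.generation)
        if gen < 0:
            raise ValueError(f"generation must be non-negative, got {gen}")
        v.setflags(write=False)
        object.__setattr__(self, "probs", v)
        object.__setattr__(self, "generation", gen)

    def __getitem__(self, status) -> float:
        return float(self.probs[int(status)])

    @classmethod
    def point_mass(cls, status: InfectionStatus, generation: int = 0) -> "StateDistribution":
        v = np.zeros(4)
        v[int(status)] = 1.0
        return cls(v, generation)

    def as_dict(self) -> dict:
        return {s.label: float(self.probs[s]) for s in STATUSES}

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps({"generation": self.generation, "probs": self.as_dict()}, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "StateDistribution":
        payload = json.loads(text)
        v = np.array([payload["probs"][s.label] for s in STATUSES], dtype=float)
        return cls(v, payload.get("generation", 0))


def build_transition_matrix(params: StrainParams) -> TransitionMatrix:
    """Build the independence-hypothesis transition matrix from per-strain rates.

    Each carried strain is transmitted with its single-infection probability,
    independently of the other strain; the uninfected row is absorbing.
    """
    p1, p2 = params.p1, params.p2
    m = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [1.0 - p1, p1, 0.0, 0.0],
            [1.0 - p2, 0.0, p2, 0.0],
            [(1.0 - p1) * (1.0 - p2), p1 * (1.0 - p2), (1.0 - p1) * p2, p1 * p2],
        ]
    )
    return TransitionMatrix(m)


def propagate(
    g0: StateDistribution, m: TransitionMatrix, n_generations: int = 1
) -> StateDistribution:
    """Propagate a state distribution ``n_generations`` steps: ``G_{n+1} = G_n · M``.

    Returns a new distribution with the generation counter advanced.  The
    vector is renormalized after the matrix products to absorb float rounding
    (the correction is at the 1e-15 level per step).
    """
    n = int(n_generations)
    if n < 0:
        raise ValueError(f"n_generations must be non-negative, got {n_generations}")
    v = g0.probs.copy()
    for _ in range(n):
        v = v @ m.entries
    v = np.clip(v, 0.0, 1.0)
    v /= v.sum()
    return StateDistribution(v, g0.generation + n)


def retention_closed_form(p: float, n: int) -> float:
    """Probability that a founding strain is still carried after ``n`` generations.

    Under the independence matrix the marginal retention of a strain with
    transmission efficiency ``p`` is simply ``p**n``, regardless of the other
    strain's rate.  Used as an analytic cross-check of :func:`propagate`.
    """
    p = _check_prob(p, "p")
    n = int(n)
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    return float(p) ** n
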