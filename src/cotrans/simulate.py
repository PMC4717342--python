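"""Stochastic isofemale-line simulation and the Monte-Carlo co-segregation test.

The segregation experiment follows isofemale lines founded by coinfected
females: a single female is kept each generation, so each line performs an
independent realization of the vertical-transmission Markov chain.  This
module simulates those realizations, builds the Monte-Carlo null distribution
of the number of coinfected lines at the final generation under the
independence hypothesis, and computes the empirical p-value for an observed
count.

Transmission is drawn per strain: a strain carried by the mother is retained
by the daughter kept for the next generation with its single-infection
probability (an independent Bernoulli event per strain).  This is exactly
equivalent to drawing the daughter's status from the corresponding row of the
independence transition matrix; the equivalence is asserted in the test
suite.  An optional ``competition`` multiplier < 1 penalizes both strains'
transmission while the line is coinfected — the alternative hypothesis the
test is designed to detect — and is never used when building the null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import STATUS_LABELS, InfectionStatus, StrainParams

__all__ = [
    "LineageTable",
    "NullDistribution",
    "EmpiricalTestResult",
    "simulate_lineages",
    "null_distribution",
    "empirical_p_value",
]

_SIDEDNESS = ("two-sided", "lower", "upper")


def _as_rng(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _observe(carry1: np.ndarray, carry2: np.ndarray, false_negative: float, rng) -> np.ndarray:
    """Status codes as scored by PCR; each carried strain can be missed.

    When ``false_negative`` is 0 (the default) no random numbers are consumed,
    so the transmission stream is unchanged by the observation step.
    """
    if false_negative > 0.0:
        seen1 = carry1 & (rng.random(carry1.shape) >= false_negative)
        seen2 = carry2 & (rng.random(carry2.shape) >= false_negative)
    else:
        seen1, seen2 = carry1, carry2
    return seen1.astype(np.int8) + 2 * seen2.astype(np.int8)


@dataclass
class LineageTable:
    """Realized infection statuses of isofemale lines across generations.

    ``records`` holds one row per line and generation with columns
    ``line_id``, ``generation`` and ``status`` (lower-case labels).
    """

    records: pd.DataFrame
    n_lines: int
    n_generations: int
    params: StrainParams
    seed: int | None = None
    competition: float = 1.0

    def status_codes(self, generation: int) -> np.ndarray:
        sub = self.records[self.records["generation"] == generation]
        sub = sub.sort_values("line_id")
        return np.array([InfectionStatus.from_label(s) for s in sub["status"]], dtype=np.int8)

    def coinfected_count(self, generation: int | None = None) -> int:
        """Number of coinfected lines at ``generation`` (default: final)."""
        if generation is None:
            generation = self.n_generations
        codes = self.status_codes(generation)
        return int(np.count_nonzero(codes == int(InfectionStatus.COINFECTED)))

    def to_tsv(self, path) -> None:
        path = Path(path)
        meta = {
            "n_lines": self.n_lines,
            "n_generations": self.n_generations,
            "p1": self.params.p1,
            "p2": self.params.p2,
            "name1": self.params.name1,
            "name2": self.params.name2,
            "seed": self.seed,
            "competition": self.competition,
        }
        with path.open("w", encoding="utf-8") as fh:
            for key, value in meta.items():
                fh.write(f"# {key}={value}\n")
            self.records.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LineageTable":
        path = Path(path)
        meta: dict[str, str] = {}
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line.lstrip("# ").rstrip("\n").partition("=")
                meta[key] = value
        records = pd.read_csv(path, sep="\t", comment="#")
        records["line_id"] = records["line_id"].astype(int)
        records["generation"] = records["generation"].astype(int)
        seed = None if meta.get("seed") in (None, "None", "") else int(meta["seed"])
        return cls(
            records=records,
            n_lines=int(meta["n_lines"]),
            n_generations=int(meta["n_generations"]),
            params=StrainParams(
                float(meta["p1"]), float(meta["p2"]),
                meta.get("name1", "strain1"), meta.get("name2", "strain2"),
            ),
            seed=seed,
            competition=float(meta.get("competition", 1.0)),
        )


def simulate_lineages(
    params: StrainParams,
    n_lines: int,
    n_generations: int,
    founder_status: InfectionStatus = InfectionStatus.COINFECTED,
    seed: int | None = None,
    *,
    competition: float = 1.0,
    false_negative: float = 0.0,
    rng: np.random.Generator | None = None,
) -> LineageTable:
    """Simulate ``n_lines`` independent isofemale lines over ``n_generations``.

    Each line starts at ``founder_status`` (generation 0, the founding
    females).  At each generation every currently carried strain is retained
    with its single-infection probability, multiplied by ``competition``
    while the line is coinfected.  Statuses are recorded every generation;
    results are reproducible given ``seed``.
    """
    n_lines = int(n_lines)
    n_generations = int(n_generations)
    if n_lines < 1:
        raise ValueError(f"n_lines must be >= 1, got {n_lines}")
    if n_generations < 0:
        raise ValueError(f"n_generations must be non-negative, got {n_generations}")
    if not 0.0 <= competition <= 1.0:
        raise ValueError(f"competition must be in [0, 1], got {competition}")
    if not 0.0 <= false_negative <= 1.0:
        raise ValueError(f"false_negative must be in [0, 1], got {false_negative}")
    gen = _as_rng(seed, rng)

    carry1 = np.full(n_lines, founder_status.carries_strain1)
    carry2 = np.full(n_lines, founder_status.carries_strain2)
    codes = np.empty((n_generations + 1, n_lines), dtype=np.int8)
    codes[0] = _observe(carry1, carry2, false_negative, gen)
    for g in range(1, n_generations + 1):
        coinf = carry1 & carry2
        eff1 = np.where(coinf, competition * params.p1, params.p1)
        eff2 = np.where(coinf, competition * params.p2, params.p2)
        carry1 &= gen.random(n_lines) < eff1
        carry2 &= gen.random(n_lines) < eff2
        codes[g] = _observe(carry1, carry2, false_negative, gen)

    labels = np.asarray(STATUS_LABELS, dtype=object)
    records = pd.DataFrame(
        {
            "line_id": np.tile(np.arange(n_lines), n_generations + 1),
            "generation": np.repeat(np.arange(n_generations + 1), n_lines),
            "status": labels[codes.reshape(-1)],
        }
    )
    return LineageTable(
        records=records,
        n_lines=n_lines,
        n_generations=n_generations,
        params=params,
        seed=seed,
        competition=competition,
    )


@dataclass
class NullDistribution:
    """Coinfected-line counts at the final generation across Monte-Carlo replicates."""

    counts: np.ndarray
    n_sims: int
    n_lines: int
    n_generations: int
    params: StrainParams
    seed: int | None = None
    competition: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 1 or len(c) != self.n_sims:
            raise ValueError("counts must be a 1-d array of length n_sims")
        if np.any(c < 0) or np.any(c > self.n_lines):
            raise ValueError("counts must lie in [0, n_lines]")
        self.counts = c

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    @property
    def sd(self) -> float:
        return float(self.counts.std(ddof=1)) if self.n_sims > 1 else 0.0

    def tabulate(self) -> pd.Series:
        """Frequency of each coinfected-line count (0..n_lines)."""
        values = np.bincount(self.counts, minlength=self.n_lines + 1)
        return pd.Series(values, index=pd.RangeIndex(self.n_lines + 1, name="count"), name="n_sims")

    def to_dict(self) -> dict:
        return {
            "n_sims": self.n_sims,
            "n_lines": self.n_lines,
            "n_generations": self.n_generations,
            "params": self.params.to_dict(),
            "seed": self.seed,
            "competition": self.competition,
            "counts": self.counts.tolist(),
        }

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def null_distribution(
    params: StrainParams,
    n_lines: int,
    n_generations: int,
    n_sims: int,
    seed: int | None = None,
    *,
    competition: float = 1.0,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Monte-Carlo distribution of the coinfected-line count under independence.

    Runs ``n_sims`` independent replicates of the full segregation experiment
    (coinfected founders) and records the number of coinfected lines at the
    final generation.  All replicates are drawn from a single generator seeded
    by ``seed``, with draws laid out replicate-major, so the distribution is
    fully reproducible given the seed.
    """
    n_sims = int(n_sims)
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    n_lines = int(n_lines)
    n_generations = int(n_generations)
    if n_lines < 1:
        raise ValueError(f"n_lines must be >= 1, got {n_lines}")
    if n_generations < 0:
        raise ValueError(f"n_generations must be non-negative, got {n_generations}")
    if not 0.0 <= competition <= 1.0:
        raise ValueError(f"competition must be in [0, 1], got {competition}")
    gen = _as_rng(seed, rng)

    shape = (n_sims, n_lines)
    carry1 = np.ones(shape, dtype=bool)
    carry2 = np.ones(shape, dtype=bool)
    for _ in range(n_generations):
        coinf = carry1 & carry2
        eff1 = np.where(coinf, competition * params.p1, params.p1)
        eff2 = np.where(coinf, competition * params.p2, params.p2)
        carry1 &= gen.random(shape) < eff1
        carry2 &= gen.random(shape) < eff2
    counts = (carry1 & carry2).sum(axis=1)
    return NullDistribution(
        counts=counts,
        n_sims=n_sims,
        n_lines=n_lines,
        n_generations=n_generations,
        params=params,
        seed=seed,
        competition=competition,
    )


@dataclass(frozen=True)
class EmpiricalTestResult:
    """Monte-Carlo test of an observed coinfected-line count against a null.

    ``p_value`` uses the add-one correction ``(r + 1) / (n_sims + 1)`` per
    tail (r = number of null counts at least as extreme as the observation),
    which keeps the p-value strictly positive; the uncorrected proportion is
    reported as ``p_value_raw``.  The two-sided p-value doubles the smaller
    tail and is capped at 1.
    """

    observed: int
    p_value: float
    p_value_raw: float
    sidedness: str
    n_sims: int
    null_mean: float
    null_sd: float

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "p_value_raw": self.p_value_raw,
            "sidedness": self.sidedness,
            "n_sims": self.n_sims,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
        }

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def empirical_p_value(
    null: NullDistribution, observed: int, sidedness: str = "two-sided"
) -> EmpiricalTestResult:
    """Empirical p-value of ``observed`` within a Monte-Carlo null distribution."""
    observed = int(observed)
    if not 0 <= observed <= null.n_lines:
        raise ValueError(
            f"observed count must lie in [0, {null.n_lines}], got {observed}"
        )
    if sidedness not in _SIDEDNESS:
        raise ValueError(f"sidedness must be one of {_SIDEDNESS}, got {sidedness!r}")
    counts = null.counts
    n = null.n_sims
    n_le = int(np.count_nonzero(counts <= observed))
    n_ge = int(np.count_nonzero(counts >= observed))
    lower = (n_le + 1) / (n + 1)
    upper = (n_ge + 1) / (n + 1)
    raw_lower = n_le / n
    raw_upper = n_ge / n
    if sidedness == "lower":
        p, raw = lower, raw_lower
    elif sidedness == "upper":
        p, raw = upper, raw_upper
    else:
        p = min(1.0, 2.0 * min(lower, upper))
        raw = min(1.0, 2.0 * min(raw_lower, raw_upper))
    return EmpiricalTestResult(
        observed=observed,
        p_value=float(p),
        p_value_raw=float(raw),
        sidedness=sidedness,
        n_sims=n,
        null_mean=null.mean,
        null_sd=null.sd,
    )
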