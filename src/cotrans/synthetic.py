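"""Synthetic-data generators emulating the three transmission experiments.

Three generators mirror the experimental designs the analysis consumes:

* **vertical** — infected mothers each produce a clutch of scored offspring;
  every maternal strain is inherited independently with its single-infection
  probability (times a competition penalty if the mother is coinfected);
* **segregation** — coinfected isofemale lines followed for several
  generations, one female kept per line and generation;
* **horizontal** — superparasitism trials in which offspring of a recipient
  line can acquire the donor's strain(s), with acquisition reduced by a
  protection factor when the recipient line is already infected.

Two alternative-hypothesis knobs make every pipeline stage testable:
``gamma`` multiplies each strain's vertical transmission while the carrier is
coinfected (``gamma = 1`` is the independence null the Monte-Carlo test
assumes), and ``rho`` multiplies horizontal-transfer success into infected
recipients (protection).  Defaults are the values the experiments support:
transmission efficiencies of 0.96 and 0.943, a base horizontal-transfer rate
of 0.75 (bracketing the observed 71-78% into uninfected recipients) and a
protection multiplier of 0.45 (bracketing the observed 26-33% into infected
recipients, the roughly twofold reduction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import InfectionStatus, StrainParams, _check_prob
from .simulate import LineageTable, NullDistribution, null_distribution, simulate_lineages

__all__ = [
    "GeneratorConfig",
    "gen_vertical_experiment",
    "gen_segregation_experiment",
    "segregation_null_counts",
    "gen_horizontal_experiment",
]

_CONFIG_KEYS = (
    "p1", "p2", "name1", "name2",
    "gamma", "rho", "horizontal", "false_negative", "vial_sd", "seed",
)


def _default_params() -> StrainParams:
    return StrainParams(0.96, 0.943, "LbFV1", "LbFV2")


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared parameters of the synthetic experiments.

    ``gamma`` — within-host competition multiplier on each strain's vertical
    transmission when the mother is coinfected (1 = independence null);
    ``rho`` — protection multiplier on horizontal acquisition when the
    recipient is already infected (1 = no protection);
    ``horizontal`` — per-offspring probability of horizontal acquisition into
    an uninfected recipient;
    ``false_negative`` — probability a carried strain is missed by PCR;
    ``vial_sd`` — standard deviation of a per-vial logit-scale random effect
    on horizontal transfer (0 disables vial-level clustering).
    """

    params: StrainParams = field(default_factory=_default_params)
    gamma: float = 1.0
    rho: float = 0.45
    horizontal: float = 0.75
    false_negative: float = 0.0
    vial_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("gamma", "rho", "horizontal", "false_negative"):
            _check_prob(getattr(self, name), name)
        if self.vial_sd < 0:
            raise ValueError(f"vial_sd must be non-negative, got {self.vial_sd}")

    def with_seed(self, seed: int | None) -> "GeneratorConfig":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        return {
            **self.params.to_dict(),
            "gamma": self.gamma,
            "rho": self.rho,
            "horizontal": self.horizontal,
            "false_negative": self.false_negative,
            "vial_sd": self.vial_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        unknown = set(d) - set(_CONFIG_KEYS)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for key in ("p1", "p2"):
            if key not in d:
                raise ValueError(f"missing config key: {key}")
        seed = d.get("seed")
        return cls(
            params=StrainParams(
                float(d["p1"]), float(d["p2"]),
                str(d.get("name1", "strain1")), str(d.get("name2", "strain2")),
            ),
            gamma=float(d.get("gamma", 1.0)),
            rho=float(d.get("rho", 0.45)),
            horizontal=float(d.get("horizontal", 0.75)),
            false_negative=float(d.get("false_negative", 0.0)),
            vial_sd=float(d.get("vial_sd", 0.0)),
            seed=None if seed in (None, "None", "") else int(seed),
        )

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        """Read a config from JSON or from ``key=value`` lines."""
        text = Path(path).read_text(encoding="utf-8").strip()
        if text.startswith("{"):
            return cls.from_dict(json.loads(text))
        d: dict[str, str] = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            d[key.strip()] = value.strip()
        return cls.from_dict(d)


def _rng_for(config: GeneratorConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def _status_frame(
    carry1: np.ndarray, carry2: np.ndarray, line_ids: np.ndarray,
    generation: int, false_negative: float, rng: np.random.Generator,
) -> pd.DataFrame:
    if false_negative > 0.0:
        carry1 = carry1 & (rng.random(carry1.shape) >= false_negative)
        carry2 = carry2 & (rng.random(carry2.shape) >= false_negative)
    codes = carry1.astype(np.int8) + 2 * carry2.astype(np.int8)
    labels = np.asarray([s.label for s in InfectionStatus], dtype=object)
    ids = np.char.add("i", np.arange(len(codes)).astype(str))
    return pd.DataFrame(
        {
            "individual_id": ids,
            "line_id": line_ids.astype(int),
            "generation": generation,
            "status": labels[codes],
        }
    )


def gen_vertical_experiment(
    config: GeneratorConfig,
    n_mothers: int = 20,
    offspring_per_mother: int = 5,
    mother_status: InfectionStatus = InfectionStatus.COINFECTED,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Offspring infection statuses from a vertical-transmission experiment.

    Each of ``n_mothers`` mothers of the given status produces
    ``offspring_per_mother`` scored daughters; each maternal strain is
    inherited independently with probability ``p * gamma`` if the mother is
    coinfected, ``p`` otherwise.  Returns an individuals table (``line_id``
    is the mother index, offspring are generation 1).
    """
    n_mothers = int(n_mothers)
    offspring_per_mother = int(offspring_per_mother)
    if n_mothers < 1 or offspring_per_mother < 1:
        raise ValueError("n_mothers and offspring_per_mother must be >= 1")
    gen = _rng_for(config, rng)
    total = n_mothers * offspring_per_mother
    penalty = config.gamma if mother_status is InfectionStatus.COINFECTED else 1.0
    q1 = config.params.p1 * penalty if mother_status.carries_strain1 else 0.0
    q2 = config.params.p2 * penalty if mother_status.carries_strain2 else 0.0
    carry1 = gen.random(total) < q1
    carry2 = gen.random(total) < q2
    line_ids = np.repeat(np.arange(n_mothers), offspring_per_mother)
    return _status_frame(carry1, carry2, line_ids, 1, config.false_negative, gen)


def gen_segregation_experiment(
    config: GeneratorConfig,
    n_lines: int = 40,
    n_generations: int = 4,
    rng: np.random.Generator | None = None,
) -> LineageTable:
    """One realization of the coinfected isofemale-line segregation experiment.

    Delegates to :func:`cotrans.simulate.simulate_lineages` with the
    competition multiplier ``gamma``; with ``gamma = 1`` the generator is the
    Monte-Carlo null model itself.
    """
    return simulate_lineages(
        config.params,
        n_lines,
        n_generations,
        founder_status=InfectionStatus.COINFECTED,
        seed=config.seed,
        competition=config.gamma,
        false_negative=config.false_negative,
        rng=rng,
    )


def segregation_null_counts(
    config: GeneratorConfig,
    n_lines: int = 40,
    n_generations: int = 4,
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Final coinfected-line counts over ``n_reps`` segregation experiments.

    Uses the same draw layout and seed policy as
    :func:`cotrans.simulate.null_distribution`, to which it reduces exactly
    when ``gamma = 1``.
    """
    return null_distribution(
        config.params,
        n_lines,
        n_generations,
        n_reps,
        seed=config.seed,
        competition=config.gamma,
        rng=rng,
    )


def gen_horizontal_experiment(
    config: GeneratorConfig,
    n_vials: int = 7,
    offspring_per_vial: int = 5,
    donor_status: InfectionStatus = InfectionStatus.STRAIN1,
    recipient_status: InfectionStatus = InfectionStatus.UNINFECTED,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Offspring statuses from a horizontal-transmission (superparasitism) trial.

    Each vial holds one recipient-line mother whose offspring are exposed to
    donor females.  Every scored offspring retains each resident (maternal)
    strain with its vertical probability and acquires the donor's strain with
    probability ``horizontal``, multiplied by ``rho`` when the recipient line
    is already infected.  A coinfected donor transmits both strains jointly
    (co-transfer is not penalized relative to single transfer).  With
    ``vial_sd > 0`` a per-vial logit-normal random effect perturbs the
    acquisition probability.
    """
    n_vials = int(n_vials)
    offspring_per_vial = int(offspring_per_vial)
    if n_vials < 1 or offspring_per_vial < 1:
        raise ValueError("n_vials and offspring_per_vial must be >= 1")
    if donor_status is InfectionStatus.UNINFECTED:
        raise ValueError("donor line must be infected")
    gen = _rng_for(config, rng)
    total = n_vials * offspring_per_vial
    line_ids = np.repeat(np.arange(n_vials), offspring_per_vial)

    protection = config.rho if recipient_status is not InfectionStatus.UNINFECTED else 1.0
    h = config.horizontal * protection
    if config.vial_sd > 0.0 and 0.0 < h < 1.0:
        logit = np.log(h / (1.0 - h)) + gen.normal(0.0, config.vial_sd, n_vials)
        h_vial = 1.0 / (1.0 + np.exp(-logit))
        h_off = h_vial[line_ids]
    else:
        h_off = np.full(total, h)

    # resident strains ride ordinary vertical transmission
    carry1 = (gen.random(total) < config.params.p1) if recipient_status.carries_strain1 \
        else np.zeros(total, dtype=bool)
    carry2 = (gen.random(total) < config.params.p2) if recipient_status.carries_strain2 \
        else np.zeros(total, dtype=bool)

    acquired = gen.random(total) < h_off
    if donor_status.carries_strain1:
        carry1 |= acquired
    if donor_status.carries_strain2:
        carry2 |= acquired
    return _status_frame(carry1, carry2, line_ids, 1, config.false_negative, gen)
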