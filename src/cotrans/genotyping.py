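"""PCR fragment-length genotyping and tabular I/O for infection records.

The two viral strains are distinguished by a deletion polymorphism in the
locus used for PCR detection: the reference strain amplifies a 399-bp
fragment, the deleted strain a 288-bp fragment (a 111-bp in-frame deletion,
shortening the predicted protein from 205 to 168 amino acids).  An
individual's infection status is therefore a pure function of the fragment
lengths observed on the gel: the long band marks strain 1, the short band
strain 2, both together coinfection, neither uninfected.

This module also reads and writes the individuals TSV used across the
package and exports the ordered presence/absence matrix used for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import InfectionStatus

__all__ = [
    "MarkerModel",
    "VariantLengths",
    "IndividualRecord",
    "AmbiguousBandError",
    "DEFAULT_MARKER",
    "variant_lengths",
    "call_genotype",
    "synthesize_bands",
    "read_individuals",
    "write_individuals",
    "order_infection_matrix",
    "write_matrix_tsv",
]

INDIVIDUAL_COLUMNS = ("individual_id", "line_id", "generation", "bands", "status")


class AmbiguousBandError(ValueError):
    """A fragment length matches both reference and variant amplicons."""


@dataclass(frozen=True)
class MarkerModel:
    """Deletion-marker arithmetic for the PCR detection locus."""

    ref_amplicon_bp: int = 399
    deletion_bp: int = 111
    ref_orf_aa: int = 205

    def __post_init__(self) -> None:
        if self.ref_amplicon_bp <= 0 or self.ref_orf_aa <= 0:
            raise ValueError("amplicon and ORF lengths must be positive")
        if self.deletion_bp < 0:
            raise ValueError("deletion length must be non-negative")
        if self.deletion_bp >= self.ref_amplicon_bp:
            raise ValueError(
                f"deletion ({self.deletion_bp} bp) must be shorter than the "
                f"amplicon ({self.ref_amplicon_bp} bp)"
            )

    @property
    def variant_amplicon_bp(self) -> int:
        return self.ref_amplicon_bp - self.deletion_bp


DEFAULT_MARKER = MarkerModel()


@dataclass(frozen=True)
class VariantLengths:
    variant_amplicon_bp: int
    variant_orf_aa: int | None
    in_frame: bool


@dataclass(frozen=True)
class IndividualRecord:
    """One scored individual: identity, observed bands, derived status."""

    individual_id: str
    line_id: int
    generation: int
    bands: frozenset[int]
    status: InfectionStatus


def variant_lengths(model: MarkerModel) -> VariantLengths:
    """Lengths implied by the deletion: variant amplicon, variant ORF, frame.

    A deletion whose length is a multiple of 3 preserves the reading frame
    and removes ``deletion_bp / 3`` codons from the predicted protein; a
    frameshifting deletion yields no protein-length prediction.
    """
    in_frame = model.deletion_bp % 3 == 0
    orf = model.ref_orf_aa - model.deletion_bp // 3 if in_frame else None
    return VariantLengths(
        variant_amplicon_bp=model.variant_amplicon_bp,
        variant_orf_aa=orf,
        in_frame=in_frame,
    )


def call_genotype(
    bands, model: MarkerModel = DEFAULT_MARKER, tolerance_bp: int = 10
) -> InfectionStatus:
    """Call an infection status from observed fragment lengths.

    A band within ``tolerance_bp`` of the reference amplicon marks strain 1;
    within ``tolerance_bp`` of the variant amplicon, strain 2.  A band that
    matches both raises :class:`AmbiguousBandError`.
    """
    if tolerance_bp < 0:
        raise ValueError(f"tolerance_bp must be non-negative, got {tolerance_bp}")
    strain1 = strain2 = False
    for band in bands:
        band = int(band)
        near1 = abs(band - model.ref_amplicon_bp) <= tolerance_bp
        near2 = abs(band - model.variant_amplicon_bp) <= tolerance_bp
        if near1 and near2:
            raise AmbiguousBandError(
                f"band of {band} bp matches both the {model.ref_amplicon_bp}-bp "
                f"and the {model.variant_amplicon_bp}-bp amplicon at "
                f"tolerance {tolerance_bp} bp"
            )
        strain1 |= near1
        strain2 |= near2
    return InfectionStatus.from_carriage(strain1, strain2)


def synthesize_bands(status: InfectionStatus, model: MarkerModel = DEFAULT_MARKER) -> set[int]:
    """Fragment lengths a clean gel would show for a given status."""
    bands: set[int] = set()
    if status.carries_strain1:
        bands.add(model.ref_amplicon_bp)
    if status.carries_strain2:
        bands.add(model.variant_amplicon_bp)
    return bands


def _format_bands(bands) -> str:
    return ";".join(str(int(b)) for b in sorted(bands))


def _parse_bands(text) -> frozenset[int]:
    text = str(text).strip()
    if not text:
        return frozenset()
    return frozenset(int(part) for part in text.split(";"))


def write_individuals(frame: pd.DataFrame, path) -> None:
    """Write an individuals table as UTF-8 TSV with header.

    Columns written (of :data:`INDIVIDUAL_COLUMNS`) are those present in the
    frame; a ``bands`` column holds semicolon-separated fragment lengths.
    """
    out = frame.copy()
    if "bands" in out.columns:
        out["bands"] = out["bands"].map(_format_bands)
    cols = [c for c in INDIVIDUAL_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in cols]
    out[cols + extra].to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_individuals(
    path,
    model: MarkerModel = DEFAULT_MARKER,
    tolerance_bp: int = 10,
) -> pd.DataFrame:
    """Read an individuals TSV, deriving statuses from bands when needed.

    Records with a failed extraction control (``control_ok`` column present
    and false) are dropped.  When the file has a ``bands`` column and no
    ``status`` column, statuses are called with :func:`call_genotype`.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"status": str}, keep_default_na=False)
    if "individual_id" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'individual_id'")
    if "control_ok" in frame.columns:
        keep = frame["control_ok"].astype(str).str.lower().isin(("true", "1", "yes"))
        frame = frame[keep].drop(columns=["control_ok"]).reset_index(drop=True)
    if "bands" in frame.columns:
        frame["bands"] = frame["bands"].map(_parse_bands)
        if "status" not in frame.columns or (frame["status"] == "").all():
            frame["status"] = frame["bands"].map(
                lambda b: call_genotype(b, model, tolerance_bp).label
            )
    if "status" not in frame.columns:
        raise ValueError(f"{path}: need a 'status' or 'bands' column")
    frame["status"].map(InfectionStatus.from_label)  # validates the vocabulary
    for col in ("line_id", "generation"):
        if col in frame.columns:
            frame[col] = frame[col].astype(int)
    return frame


_ORDER_PRIORITY = {
    InfectionStatus.COINFECTED.label: 0,
    InfectionStatus.STRAIN1.label: 1,
    InfectionStatus.STRAIN2.label: 2,
    InfectionStatus.UNINFECTED.label: 3,
}


def order_infection_matrix(
    frame: pd.DataFrame, name1: str = "strain1", name2: str = "strain2"
) -> pd.DataFrame:
    """Presence/absence matrix (individuals x strains) ordered for display.

    Rows are sorted coinfected first, then strain-1 only, strain-2 only,
    uninfected; the sort is stable, so individuals with the same status keep
    their input order.  Column sums (per-strain prevalences) are unchanged by
    the reordering.
    """
    if frame.empty:
        raise ValueError("cannot order an empty record table")
    carriage = [
        (InfectionStatus.from_label(s).carries_strain1,
         InfectionStatus.from_label(s).carries_strain2)
        for s in frame["status"]
    ]
    matrix = pd.DataFrame(
        {
            name1: np.array([int(c1) for c1, _ in carriage]),
            name2: np.array([int(c2) for _, c2 in carriage]),
        },
        index=pd.Index(frame["individual_id"], name="individual_id"),
    )
    priority = frame["status"].map(_ORDER_PRIORITY).to_numpy()
    order = np.argsort(priority, kind="stable")
    return matrix.iloc[order]


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", encoding="utf-8")
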