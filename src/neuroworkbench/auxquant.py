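"""Small quantitative procedures: CRISPR clone calls and editing-probability
model, and Western-blot normalisation with the soft/stiff ratio and its
linearity-based discard rule."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "CloneStatus",
    "AmpliconCall",
    "EditingModel",
    "classify_clone",
    "editing_fraction",
    "unedited_probability",
    "blot_ratio",
]


class CloneStatus(str, Enum):
    CLEAN = "clean"
    POINT_MUTATION = "point_mutation"
    INSERTION = "insertion"
    DELETION = "deletion"
    MULTI_BASE = "multi_base"
    VECTOR_ONLY = "vector_only"


@dataclass
class AmpliconCall:
    clone_id: str
    status: CloneStatus

    @property
    def is_mutated(self) -> bool:
        return self.status in (
            CloneStatus.POINT_MUTATION,
            CloneStatus.INSERTION,
            CloneStatus.DELETION,
            CloneStatus.MULTI_BASE,
        )

    @property
    def is_usable(self) -> bool:
        """Vector-only clones carry no amplicon and leave every denominator."""
        return self.status is not CloneStatus.VECTOR_ONLY


@dataclass
class EditingModel:
    """Independent-guide editing model.

    With per-guide mutation probability p and n independently acting guides,
    the chance that a clone carries no mutation is P_WT = (1 - p)^n and the
    chance of at least one mutation is 1 - P_WT.
    """

    p_per_guide: float
    n_guides: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_per_guide <= 1:
            raise ValueError("p_per_guide must lie in [0, 1]")
        if self.n_guides < 0:
            raise ValueError("n_guides must be >= 0")

    @property
    def p_wt(self) -> float:
        return (1.0 - self.p_per_guide) ** self.n_guides

    @property
    def p_mut_total(self) -> float:
        return 1.0 - self.p_wt


def _aligner(match: float = 2.0, mismatch: float = -1.0,
             gap_open: float = -5.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def classify_clone(
    clone_seq: str, reference: str, clone_id: str = "", min_identity: float = 0.5
) -> AmpliconCall:
    """Call a Sanger clone against the amplicon reference.

    Global pairwise alignment; identical -> clean; substitutions only: one ->
    point mutation, several -> multi-base mutation; any gap -> insertion (if
    the clone is longer) or deletion; alignment identity below
    ``min_identity`` -> vector-only (the clone carries only cloning-vector
    sequence and is unusable).
    """
    clone_seq = str(clone_seq).upper()
    reference = str(reference).upper()
    if clone_seq == reference:
        return AmpliconCall(clone_id, CloneStatus.CLEAN)
    aln = _aligner().align(reference, clone_seq)[0]
    ref_a, clone_a = aln[0], aln[1]
    matches = sum(x == y and x != "-" for x, y in zip(ref_a, clone_a))
    identity = matches / max(len(reference), len(clone_seq))
    if identity < min_identity:
        return AmpliconCall(clone_id, CloneStatus.VECTOR_ONLY)
    has_gap_ref = "-" in ref_a
    has_gap_clone = "-" in clone_a
    if has_gap_ref and not has_gap_clone:
        return AmpliconCall(clone_id, CloneStatus.INSERTION)
    if has_gap_clone and not has_gap_ref:
        return AmpliconCall(clone_id, CloneStatus.DELETION)
    if has_gap_ref and has_gap_clone:
        return AmpliconCall(clone_id, CloneStatus.MULTI_BASE)
    n_sub = sum(x != y for x, y in zip(ref_a, clone_a))
    status = CloneStatus.POINT_MUTATION if n_sub == 1 else CloneStatus.MULTI_BASE
    return AmpliconCall(clone_id, status)


def editing_fraction(calls: list[AmpliconCall]) -> int:
    """Editing percentage, rounded to the nearest integer.

    Vector-only clones are excluded from the denominator (4 mutated of 13
    usable clones -> 31%).
    """
    usable = [c for c in calls if c.is_usable]
    if not usable:
        raise ValueError("no usable clones")
    mutated = sum(c.is_mutated for c in usable)
    return int(round(100.0 * mutated / len(usable)))


def unedited_probability(p_per_guide: float, n_guides: int) -> EditingModel:
    """Probability model of finding a mutation-free clone under n guides."""
    return EditingModel(p_per_guide=p_per_guide, n_guides=n_guides)


def blot_ratio(bands: pd.DataFrame, band_role: str = "tetramer") -> pd.DataFrame:
    """Soft/stiff expression ratios from Western-blot band tables.

    ``bands`` columns: replicate, blot, concentration, condition
    ("soft"/"stiff"), band_signal, tps_signal, band_role.  Band signals are
    normalised by the total-protein stain; the median normalised signal is
    taken per (replicate, blot, concentration, condition); the ratio is
    r = median_soft / median_stiff per (replicate, blot, concentration).
    A blot is discarded when its two lysate concentrations disagree about
    the side of 1 (one r < 1, the other r > 1), which indicates signals
    outside the linear range.  Only bands of ``band_role`` are quantified.

    Returns one row per (replicate, blot, concentration) with columns
    r and discard.
    """
    required = {
        "replicate", "blot", "concentration", "condition",
        "band_signal", "tps_signal", "band_role",
    }
    missing = required - set(bands.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = bands[bands["band_role"] == band_role].copy()
    if df.empty:
        raise ValueError(f"no bands with role {band_role!r}")
    if (df["tps_signal"] <= 0).any():
        raise ValueError("total-protein stain signals must be positive")
    df["normalised"] = df["band_signal"] / df["tps_signal"]
    med = (
        df.groupby(["replicate", "blot", "concentration", "condition"])["normalised"]
        .median()
        .unstack("condition")
    )
    if not {"soft", "stiff"} <= set(med.columns):
        raise ValueError("need both 'soft' and 'stiff' conditions")
    out = med.reset_index()
    out["r"] = out["soft"] / out["stiff"]
    discard = (
        out.groupby(["replicate", "blot"])["r"]
        .transform(lambda r: (r < 1).any() and (r > 1).any())
        .astype(bool)
    )
    out["discard"] = discard
    return out[["replicate", "blot", "concentration", "r", "discard"]]
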