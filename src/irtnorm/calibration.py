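"""iRT scale definition and extended anchor-set construction.

The iRT scale is anchored by two reference peptides: the peptide defining
iRT = 0 and the peptide defining iRT = 100.  A plain linear map through
those two (RT, iRT) points converts mean retention times to iRT.

An *extended* calibration set is built from replicate runs of a complex
digest: only precursors identified in every replicate are kept, their mean
and SD of apex RT are computed, the RT range is cut into equal-width bins,
and within each bin only the fraction of precursors with the lowest RT SD
is retained (the kit peptides are exempt from this filter).  Surviving
precursors are assigned iRT values through the two-anchor map, producing a
database of thousands of anchor points for segmented regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .regression import LinearFit

__all__ = [
    "CalibrationError",
    "KitPeptide",
    "CalibrationSet",
    "DEFAULT_KIT",
    "precursor_id",
    "sequence_of",
    "two_anchor_calibration",
    "kit_calibration",
    "extend_calibration_set",
    "match_to_calibration_db",
]


class CalibrationError(ValueError):
    """Raised when the scale-defining anchors cannot be established."""


@dataclass(frozen=True)
class KitPeptide:
    """A calibration-kit peptide with its assigned iRT value."""

    sequence: str
    irt: float


#: The two scale-defining kit peptides. The full kit has 11 peptides, but
#: only the iRT = 0 and iRT = 100 peptides define the scale; the remaining
#: published iRT values are supplied by the user when available.
DEFAULT_KIT = (KitPeptide("iRT-pep-b", 0.0), KitPeptide("iRT-pep-l", 100.0))


def precursor_id(modified_sequence: str, charge: int) -> str:
    """Canonical precursor identifier: ``<modified sequence>/<charge>``."""
    return f"{modified_sequence}/{int(charge)}"


def sequence_of(pid: str) -> str:
    """Modified sequence part of a canonical precursor identifier."""
    return pid.rsplit("/", 1)[0]


def two_anchor_calibration(rt_b: float, rt_l: float) -> LinearFit:
    """Linear iRT ~ RT map sending ``rt_b`` to 0 and ``rt_l`` to 100.

    ``rt_b`` and ``rt_l`` are the mean retention times (minutes) of the
    scale-defining kit peptides.

    Raises
    ------
    CalibrationError
        If the two anchor RTs coincide or are not finite.
    """
    if not (math.isfinite(rt_b) and math.isfinite(rt_l)):
        raise CalibrationError("anchor retention times must be finite")
    if rt_b == rt_l:
        raise CalibrationError(
            f"degenerate anchors: rt_b == rt_l == {rt_b}; scale undefined"
        )
    slope = 100.0 / (rt_l - rt_b)
    return LinearFit(slope=slope, intercept=-slope * rt_b)


def kit_calibration(kit_rts: Mapping[str, float],
                    kit: Iterable[KitPeptide]) -> LinearFit:
    """Least-squares iRT ~ RT over a full kit with known iRT values.

    Optional alternative to the exact two-anchor map when all kit iRTs are
    known.  ``kit_rts`` maps kit sequence -> observed mean RT (minutes).
    """
    kit = list(kit)
    pairs = [(kit_rts[k.sequence], k.irt) for k in kit if k.sequence in kit_rts]
    if len(pairs) < 2:
        raise CalibrationError(
            f"need >= 2 observed kit peptides, found {len(pairs)}"
        )
    rts = np.array([p[0] for p in pairs])
    irts = np.array([p[1] for p in pairs])
    if np.all(rts == rts[0]):
        raise CalibrationError("degenerate anchors: all kit RTs identical")
    slope, intercept = np.polyfit(rts, irts, 1)
    return LinearFit(slope=float(slope), intercept=float(intercept))


@dataclass
class CalibrationSet:
    """An iRT anchor database: per-precursor iRT with RT replicate statistics.

    ``entries`` columns: ``precursor_id``, ``irt``, ``rt_mean`` (minutes),
    ``rt_sd`` (minutes).  ``provenance`` records construction parameters.
    """

    entries: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"precursor_id", "irt", "rt_mean", "rt_sd"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"calibration set missing columns: {sorted(missing)}")
        if self.entries["precursor_id"].duplicated().any():
            raise ValueError("calibration set has duplicate precursor identifiers")

    def __len__(self) -> int:
        return len(self.entries)

    def irt_of(self) -> pd.Series:
        return self.entries.set_index("precursor_id")["irt"]


def _kit_mask(pids: pd.Series, kit: Iterable[KitPeptide]) -> pd.Series:
    kit_seqs = {k.sequence for k in kit}
    return pids.map(lambda p: sequence_of(p) in kit_seqs)


def extend_calibration_set(observations: pd.DataFrame,
                           kit: Iterable[KitPeptide] = DEFAULT_KIT,
                           n_bins: int = 20,
                           keep_fraction: float = 0.8) -> CalibrationSet:
    """Build the extended anchor set from replicate observations.

    Parameters
    ----------
    observations : DataFrame with columns ``run_id``, ``precursor_id``,
        ``rt_apex`` (apex retention time, minutes).
    kit : calibration-kit peptides; must include the scale-defining
        iRT = 0 and iRT = 100 peptides, observed in every run.
    n_bins : number of equal-width RT bins spanning first to last eluter.
    keep_fraction : per-bin fraction of precursors (lowest RT SD) retained;
        floor with a minimum of one per non-empty bin. Kit peptides are
        always retained regardless of their SD.

    Raises
    ------
    CalibrationError
        If the scale-defining kit anchors are not observed in all runs.
    """
    kit = list(kit)
    if not (0 < keep_fraction <= 1):
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    required = {"run_id", "precursor_id", "rt_apex"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    n_runs = observations["run_id"].nunique()
    if n_runs < 3:
        raise ValueError(f"need >= 3 replicate runs, got {n_runs}")

    # precursors identified in every replicate acquisition
    per_prec = observations.groupby("precursor_id")["rt_apex"]
    stats = per_prec.agg(rt_mean="mean", rt_sd=lambda s: s.std(ddof=1),
                         n_runs="size")
    complete = stats[stats["n_runs"] == n_runs].drop(columns="n_runs")
    if complete.empty:
        raise CalibrationError("no precursor observed in all replicate runs")
    complete = complete.reset_index()

    is_kit = _kit_mask(complete["precursor_id"], kit)

    # equal-width RT bins from first to last eluting precursor, last bin
    # closed on the right; lowest-SD keep_fraction retained per bin
    edges = np.linspace(complete["rt_mean"].min(), complete["rt_mean"].max(),
                        n_bins + 1)
    if edges[0] == edges[-1]:
        bin_idx = pd.Series(0, index=complete.index)
    else:
        bin_idx = pd.Series(
            np.clip(np.searchsorted(edges, complete["rt_mean"], side="right") - 1,
                    0, n_bins - 1),
            index=complete.index,
        )
    keep = is_kit.copy()
    for _, idx in complete.groupby(bin_idx).groups.items():
        k = len(idx)
        n_keep = max(1, math.floor(keep_fraction * k))
        ranked = complete.loc[idx].sort_values("rt_sd", kind="stable").index
        keep.loc[ranked[:n_keep]] = True
    selected = complete[keep].reset_index(drop=True)

    fit = _scale_fit(selected, kit)
    selected = selected.assign(irt=fit(selected["rt_mean"].to_numpy()))
    return CalibrationSet(
        entries=selected[["precursor_id", "irt", "rt_mean", "rt_sd"]],
        provenance={
            "n_runs": int(n_runs),
            "n_bins": int(n_bins),
            "keep_fraction": float(keep_fraction),
            "n_input_precursors": int(len(stats)),
            "n_complete": int(len(complete)),
            "calibration": {"slope": fit.slope, "intercept": fit.intercept},
        },
    )


def _scale_fit(selected: pd.DataFrame, kit: list[KitPeptide]) -> LinearFit:
    by_seq = {sequence_of(p): rt for p, rt in
              zip(selected["precursor_id"], selected["rt_mean"])}
    anchors = {k.irt: by_seq.get(k.sequence) for k in kit if k.irt in (0.0, 100.0)}
    rt_b, rt_l = anchors.get(0.0), anchors.get(100.0)
    if rt_b is None or rt_l is None:
        raise CalibrationError(
            "scale-defining kit peptides (iRT 0 and iRT 100) not present "
            "after filtering; cannot calibrate"
        )
    return two_anchor_calibration(rt_b, rt_l)


def match_to_calibration_db(run_peptides: pd.DataFrame,
                            db: CalibrationSet) -> pd.DataFrame:
    """Match run identifications against the anchor database.

    ``run_peptides`` needs columns ``precursor_id`` and ``rt``.  Returns the
    inner join as anchor points with columns ``precursor_id``, ``x`` (the
    run RT) and ``y`` (the database iRT), in run order.  Empty overlap
    yields an empty frame; the caller decides the fallback.
    """
    required = {"precursor_id", "rt"}
    missing = required - set(run_peptides.columns)
    if missing:
        raise ValueError(f"run_peptides missing columns: {sorted(missing)}")
    irt = db.irt_of()
    matched = run_peptides["precursor_id"].map(irt)
    hit = matched.notna()
    return pd.DataFrame({
        "precursor_id": run_peptides.loc[hit, "precursor_id"].to_numpy(),
        "x": run_peptides.loc[hit, "rt"].to_numpy(dtype=float),
        "y": matched[hit].to_numpy(dtype=float),
    })
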