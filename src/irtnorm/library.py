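"""Spectral library construction from annotated PSM tables.

A spectral library records, per peptide precursor, the fragment ions to
extract (m/z and relative intensity) and a normalized retention time (iRT).
Construction rules:

* fragment ions below 300 m/z, above 1800 m/z, or covering fewer than three
  residues are discarded (neutral-loss fragments are allowed);
* at most the six most intense surviving fragments are kept, and precursors
  with fewer than three surviving fragments are dropped;
* per run, PSM retention times are converted to iRT through a segmented
  regression against the anchor database, and the library iRT is the median
  across runs;
* fragment intensities are taken from a single source spectrum: the run
  with the best (lowest) PSM score, or the median-RT run when no scores are
  present.

Fragment and precursor m/z values are validated with standard monoisotopic
residue masses (b ions: summed residue masses + proton; y ions: summed
residue masses + water + proton).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .calibration import CalibrationSet, match_to_calibration_db
from .regression import (
    DegenerateInputError,
    MIN_ANCHORS_LIBRARY,
    SegmentedTheilSenRegressor,
)

__all__ = [
    "LibraryBuildError",
    "FRAGMENT_MZ_MIN",
    "FRAGMENT_MZ_MAX",
    "MIN_FRAGMENT_ORDINAL",
    "MIN_FRAGMENTS",
    "MAX_FRAGMENTS",
    "LibraryEntry",
    "SpectralLibrary",
    "filter_fragments",
    "consensus_irt",
    "fragment_mz",
    "precursor_mz",
    "assemble_library",
]

logger = logging.getLogger(__name__)

FRAGMENT_MZ_MIN = 300.0   # Th, inclusive
FRAGMENT_MZ_MAX = 1800.0  # Th, inclusive
MIN_FRAGMENT_ORDINAL = 3  # minimum residues covered by a fragment
MIN_FRAGMENTS = 3
MAX_FRAGMENTS = 6

#: Columns of a fragment annotation table.
FRAGMENT_COLUMNS = ("series", "ordinal", "fragment_charge", "mz", "intensity")


class LibraryBuildError(ValueError):
    """Raised when a spectral library cannot be assembled."""


def filter_fragments(candidates: pd.DataFrame,
                     mz_min: float = FRAGMENT_MZ_MIN,
                     mz_max: float = FRAGMENT_MZ_MAX,
                     min_ordinal: int = MIN_FRAGMENT_ORDINAL,
                     max_fragments: int = MAX_FRAGMENTS) -> pd.DataFrame:
    """Apply the library fragment filters to candidate ions.

    Keeps fragments with ``mz_min <= mz <= mz_max`` (bounds inclusive) and
    ``ordinal >= min_ordinal`` (neutral-loss fragments pass on the same
    terms), sorts by intensity descending (ties: lower m/z first) and
    truncates to ``max_fragments``.  Empty input yields an empty frame.
    """
    missing = {"series", "ordinal", "mz", "intensity"} - set(candidates.columns)
    if missing:
        raise ValueError(f"fragment table missing columns: {sorted(missing)}")
    mz = candidates["mz"].astype(float)
    ok = (mz >= mz_min) & (mz <= mz_max) & (candidates["ordinal"].astype(int)
                                            >= min_ordinal)
    kept = candidates[ok]
    kept = kept.sort_values(["intensity", "mz"], ascending=[False, True],
                            kind="stable")
    return kept.head(max_fragments).reset_index(drop=True)


def consensus_irt(per_run_irts) -> float:
    """Median iRT across runs (mean of the central pair for even counts)."""
    vals = np.asarray(list(per_run_irts), dtype=float)
    if vals.size == 0:
        raise ValueError("consensus iRT undefined for an empty value list")
    return float(np.median(vals))


def fragment_mz(sequence: str, series: str, ordinal: int, charge: int) -> float:
    """Monoisotopic m/z of a b or y fragment of an unmodified peptide.

    b_k covers the first ``ordinal`` residues, y_k the last ``ordinal``.
    """
    if series not in ("b", "y"):
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    if not 1 <= ordinal < len(sequence):
        raise ValueError(
            f"ordinal {ordinal} out of range for a {len(sequence)}-residue peptide"
        )
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    for ch in sequence:
        if ch not in _pmass.std_aa_mass:
            raise ValueError(f"unknown residue {ch!r} in sequence {sequence!r}")
    sub = sequence[:ordinal] if series == "b" else sequence[-ordinal:]
    return float(_pmass.fast_mass(sub, ion_type=series, charge=charge))


def precursor_mz(sequence: str, charge: int) -> float:
    """Monoisotopic precursor m/z of an unmodified peptide."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    for ch in sequence:
        if ch not in _pmass.std_aa_mass:
            raise ValueError(f"unknown residue {ch!r} in sequence {sequence!r}")
    return float(_pmass.fast_mass(sequence, charge=charge))


@dataclass
class LibraryEntry:
    """One precursor's library record: identity, iRT and ranked fragments."""

    precursor_id: str
    modified_sequence: str
    sequence: str
    charge: int
    precursor_mz: float
    irt: float
    fragments: pd.DataFrame  # intensity-descending, FRAGMENT_COLUMNS (+extras)
    protein_id: str = "unknown"


@dataclass
class SpectralLibrary:
    """A set of unique-precursor library entries with build provenance."""

    entries: list[LibraryEntry]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [e.precursor_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("spectral library has duplicate precursor entries")

    def __len__(self) -> int:
        return len(self.entries)

    def to_openswath(self) -> pd.DataFrame:
        """Long-format transition list in the OpenSWATH TSV dialect."""
        rows = []
        for e in self.entries:
            for _, fr in e.fragments.iterrows():
                rows.append({
                    "PrecursorMz": e.precursor_mz,
                    "ProductMz": float(fr["mz"]),
                    "LibraryIntensity": float(fr["intensity"]),
                    "NormalizedRetentionTime": e.irt,
                    "PeptideSequence": e.sequence,
                    "ModifiedPeptideSequence": e.modified_sequence,
                    "PrecursorCharge": e.charge,
                    "FragmentType": str(fr["series"]),
                    "FragmentSeriesNumber": int(fr["ordinal"]),
                    "FragmentCharge": int(fr["fragment_charge"]),
                    "ProteinId": e.protein_id,
                })
        return pd.DataFrame(rows, columns=[
            "PrecursorMz", "ProductMz", "LibraryIntensity",
            "NormalizedRetentionTime", "PeptideSequence",
            "ModifiedPeptideSequence", "PrecursorCharge", "FragmentType",
            "FragmentSeriesNumber", "FragmentCharge", "ProteinId",
        ])


def _source_run(group: pd.DataFrame) -> pd.Series:
    """Pick the PSM row providing the fragment pattern for a precursor."""
    if group["score"].notna().any():
        scored = group[group["score"].notna()]
        return scored.loc[scored["score"].idxmin()]
    ranked = group.sort_values("rt_apex", kind="stable")
    return ranked.iloc[(len(ranked) - 1) // 2]  # median-RT run (lower middle)


def assemble_library(psms: pd.DataFrame, fragments: pd.DataFrame,
                     calibration_db: CalibrationSet,
                     min_anchors: int = MIN_ANCHORS_LIBRARY) -> SpectralLibrary:
    """Assemble a spectral library from per-run PSM and fragment tables.

    Parameters
    ----------
    psms : DataFrame with columns ``run_id``, ``precursor_id``,
        ``modified_sequence``, ``sequence``, ``charge``, ``rt_apex``
        (minutes) and optional ``score`` (lower is better) and
        ``protein_id``.
    fragments : DataFrame with columns ``run_id``, ``precursor_id``,
        ``series``, ``ordinal``, ``fragment_charge``, ``mz``, ``intensity``
        and optional ``neutral_loss``.
    calibration_db : the iRT anchor database used to convert each run's
        retention times to iRT (segmented regression with ``min_anchors``,
        global-linear fallback below it).

    Raises
    ------
    LibraryBuildError
        When no run shares enough anchors with the database to fit any
        RT -> iRT mapping.
    """
    required = {"run_id", "precursor_id", "modified_sequence", "sequence",
                "charge", "rt_apex"}
    missing = required - set(psms.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    psms = psms.copy()
    if "score" not in psms.columns:
        psms["score"] = np.nan
    if "protein_id" not in psms.columns:
        psms["protein_id"] = "unknown"

    # per-run RT -> iRT conversion against the anchor database
    converted = []
    for run_id, run in psms.groupby("run_id", sort=False):
        anchors = match_to_calibration_db(
            run.rename(columns={"rt_apex": "rt"})[["precursor_id", "rt"]],
            calibration_db,
        )
        try:
            model = SegmentedTheilSenRegressor(
                mode="rt_to_irt", min_anchors=min_anchors
            ).fit(anchors["x"], anchors["y"])
        except DegenerateInputError:
            logger.warning(
                "run %s: %d usable calibration anchors; run skipped",
                run_id, len(anchors))
            continue
        logger.info("run %s: %d anchors, %s", run_id, len(anchors),
                    "segmented" if model.fallback_ is None else "linear fallback")
        converted.append(run.assign(irt=model.predict(
            run["rt_apex"].to_numpy(dtype=float))))
    if not converted:
        raise LibraryBuildError(
            "no run overlaps the calibration database; cannot build library"
        )
    psms = pd.concat(converted, ignore_index=True)

    frag_by_run = fragments.groupby(["run_id", "precursor_id"], sort=False)
    entries = []
    for pid, group in psms.groupby("precursor_id", sort=False):
        irt = consensus_irt(group["irt"])
        src = _source_run(group)
        key = (src["run_id"], pid)
        if key not in frag_by_run.groups:
            continue
        kept = filter_fragments(frag_by_run.get_group(key))
        if len(kept) < MIN_FRAGMENTS:
            continue
        entries.append(LibraryEntry(
            precursor_id=pid,
            modified_sequence=str(src["modified_sequence"]),
            sequence=str(src["sequence"]),
            charge=int(src["charge"]),
            precursor_mz=precursor_mz(str(src["sequence"]), int(src["charge"])),
            irt=irt,
            fragments=kept,
            protein_id=str(src["protein_id"]),
        ))
    logger.info("library: %d precursors from %d PSM groups", len(entries),
                psms["precursor_id"].nunique())
    return SpectralLibrary(entries=entries, meta={
        "n_runs": int(psms["run_id"].nunique()),
        "min_anchors": int(min_anchors),
        "n_calibration_anchors": len(calibration_db),
    })
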