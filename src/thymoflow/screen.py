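"""Surface-marker screen analytics.

Implements the screening workflow used to discover TEC markers: per-well MFI
per reference population, two-population MFI-ratio ranking, top-N candidate
selection with an absolute-MFI floor, and inter-donor reproducibility
scoring (CV of a marker's MFI across donors). MFIs are arithmetic means on
the raw instrument scale by default; median and geometric mean are exposed
for robustness studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, StateError

logger = logging.getLogger("thymoflow")


@dataclass
class ScreenPlate:
    """One screening plate: per-marker MFIs in each reference population.

    ``wells`` is a DataFrame indexed by marker with one column per
    reference population.
    """

    donor_id: str
    wells: pd.DataFrame

    def __post_init__(self):
        if self.wells.index.has_duplicates:
            raise ConfigError("marker names must be unique within a plate")
        if (self.wells.to_numpy() < 0).any():
            raise ConfigError("MFIs must be non-negative")

    @property
    def n_markers(self) -> int:
        return len(self.wells)

    @property
    def populations(self) -> list:
        return list(self.wells.columns)

    def to_tsv(self, path):
        tidy = (self.wells.reset_index()
                .melt(id_vars="marker", var_name="population", value_name="mfi"))
        tidy.insert(0, "donor_id", self.donor_id)
        tidy.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path):
        tidy = pd.read_csv(path, sep="\t")
        donor = str(tidy["donor_id"].iloc[0]) if len(tidy) else ""
        wells = tidy.pivot(index="marker", columns="population", values="mfi")
        wells.columns.name = None
        return cls(donor_id=donor, wells=wells)


@dataclass
class ScreenRanking:
    """Markers ranked by MFI(pop_a)/MFI(pop_b), descending, ties alphabetical."""

    pop_a: str
    pop_b: str
    rows: pd.DataFrame  # columns: marker, mfi_a, mfi_b, ratio, infinite, rank
    excluded: list = field(default_factory=list)  # markers with MFI 0 in both


@dataclass
class CandidateSet:
    high_end: list
    low_end: list
    mfi_floor: float
    excluded_by_floor: list


def population_mfi(table, member_mask, marker, statistic="mean") -> float:
    """Summary fluorescence intensity of a marker over a selected population.

    Computed on the raw scale (the screen's ranking logic operates on
    instrument-scale means); a transformed table is a state error.
    """
    if table.scale_state != "raw":
        raise StateError("MFI must be computed on raw-scale intensities")
    member_mask = np.asarray(member_mask, dtype=bool)
    values = table.values(marker)[member_mask]
    if values.size == 0:
        raise DataError("empty population selection for MFI")
    if statistic == "mean":
        return float(values.mean())
    if statistic == "median":
        return float(np.median(values))
    if statistic == "geomean":
        if (values <= 0).any():
            raise DataError("geometric mean requires strictly positive intensities")
        return float(np.exp(np.log(values).mean()))
    raise ConfigError(f"unknown MFI statistic {statistic!r}")


def rank_markers(plate: ScreenPlate, pop_a: str, pop_b: str) -> ScreenRanking:
    """Rank every marker by the MFI ratio between two reference populations.

    Zero handling: MFI(pop_b) = 0 gives an infinite ratio sorted above all
    finite rows and flagged; both zero excludes the row with a log entry.
    """
    for pop in (pop_a, pop_b):
        if pop not in plate.wells.columns:
            raise DataError(f"population {pop!r} absent from plate {plate.donor_id!r}")
    a = plate.wells[pop_a]
    b = plate.wells[pop_b]
    both_zero = (a == 0) & (b == 0)
    excluded = sorted(plate.wells.index[both_zero])
    if excluded:
        logger.info("excluded %d markers with zero MFI in both populations: %s",
                    len(excluded), excluded)
    keep = ~both_zero
    with np.errstate(divide="ignore"):
        ratio = np.where(b[keep] > 0, a[keep] / b[keep], np.inf)
    rows = pd.DataFrame({
        "marker": plate.wells.index[keep],
        "mfi_a": a[keep].to_numpy(),
        "mfi_b": b[keep].to_numpy(),
        "ratio": ratio,
        "infinite": ~np.isfinite(ratio),
    })
    rows = rows.sort_values(["ratio", "marker"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    rows["rank"] = np.arange(1, len(rows) + 1)
    return ScreenRanking(pop_a=pop_a, pop_b=pop_b, rows=rows, excluded=excluded)


def select_candidates(ranking: ScreenRanking, top_n: int, mfi_floor: float) -> CandidateSet:
    """Top-N markers from each end of the ratio spectrum, dropping markers
    whose best absolute MFI falls below the floor (listed with reason)."""
    if top_n < 1:
        raise ConfigError("top_n must be >= 1")
    n = len(ranking.rows)
    if top_n > n:
        logger.warning("top_n=%d exceeds %d ranked markers; clamping", top_n, n)
        top_n = n
    rows = ranking.rows
    best = rows[["mfi_a", "mfi_b"]].max(axis=1)
    passes = best >= mfi_floor

    top = rows.iloc[:top_n]
    bottom = rows.iloc[::-1].iloc[:top_n]
    high_end = list(top.loc[passes.iloc[:top_n].to_numpy(), "marker"])
    excluded = list(top.loc[~passes.iloc[:top_n].to_numpy(), "marker"])
    low_end, seen = [], set(high_end)
    for marker, ok in zip(bottom["marker"], passes.iloc[::-1].iloc[:top_n]):
        if marker in seen:
            continue  # overlap possible only when 2*top_n > n; high end wins
        (low_end if ok else excluded).append(marker)
    return CandidateSet(high_end=high_end, low_end=low_end,
                        mfi_floor=mfi_floor, excluded_by_floor=excluded)


def reproducibility_score(plates, markers, population) -> pd.DataFrame:
    """Inter-donor reproducibility: CV (sample SD / mean) of each marker's
    MFI in one population across donor plates, most reproducible first."""
    if len(plates) < 2:
        raise DataError("reproducibility needs plates from at least 2 donors")
    rows = []
    for marker in markers:
        values = []
        for plate in plates:
            if marker not in plate.wells.index:
                raise DataError(f"marker {marker!r} missing from plate {plate.donor_id!r}")
            if population not in plate.wells.columns:
                raise DataError(f"population {population!r} missing from plate {plate.donor_id!r}")
            values.append(plate.wells.at[marker, population])
        values = np.asarray(values, dtype=float)
        mean = values.mean()
        cv = float(values.std(ddof=1) / mean) if mean > 0 else np.nan
        rows.append({"marker": marker, "cv": cv, "n_donors": len(values)})
    report = pd.DataFrame(rows).sort_values("cv", na_position="last", kind="mergesort")
    return report.reset_index(drop=True)


def plot_marker_histograms(table, markers, path, *, bins=100):
    """Diagnostic per-marker intensity histograms for human review of
    candidate markers (the screen's final visual-inspection step is manual)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(markers), 1, figsize=(6, 2.2 * len(markers)), squeeze=False)
    for ax, marker in zip(axes.ravel(), markers):
        ax.hist(np.arcsinh(table.values(marker) / 150.0), bins=bins)
        ax.set_title(marker)
        ax.set_xlabel("asinh intensity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
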