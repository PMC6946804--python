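"""Mass-difference statistics for FTICR-MS peak lists.

Ultrahigh-resolution mass spectra of dissolved organic matter resolve
peak pairs whose m/z spacing equals the exact mass of a single element
gain or loss.  This module counts unordered peak pairs separated by one
oxygen (15.994915 Da — the mass shift a flavin-dependent monooxygenase
imprints) or one carbon (12 Da exactly), and reports the O:C pair-count
ratio per sample and its depth profile.  Matching uses a ppm tolerance
relative to the heavier peak (default 1 ppm, typical FTICR mass
accuracy); an absolute-Da tolerance is available instead.

Peaks are treated as neutral monoisotopic masses; charge deconvolution
and molecular-formula assignment are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cnp.simulate import CARBON_MASS, OXYGEN_MASS, PeakList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Transformation:
    name: str
    delta_mass: float  # Da, > 0

    def __post_init__(self):
        if self.delta_mass <= 0:
            raise ValueError("delta_mass must be > 0")


OXYGEN = Transformation("O", OXYGEN_MASS)
CARBON = Transformation("C", CARBON_MASS)


@dataclass
class TransformationCounts:
    sample_id: str
    counts: dict[str, int]
    o_to_c_ratio: float  # NaN when the C count is 0


def count_mass_differences(peaks: PeakList, t: Transformation,
                           tol_ppm: float = 1.0,
                           tol_da: float | None = None) -> int:
    """Unordered peak pairs (a, b), b > a, with (b - a) within tolerance of delta_mass.

    Tolerance is ``tol_ppm`` ppm of the heavier peak b, or a fixed
    ``tol_da`` in Da when given.  Sorted-array window search, O(n log n);
    equivalent to the naive all-pairs double loop.
    """
    if tol_da is None and tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    mz = peaks.mz
    n = len(mz)
    if n < 2:
        return 0
    tol = np.full(n, tol_da) if tol_da is not None else tol_ppm * 1e-6 * mz
    # partners a for each b lie in [b - delta - tol_b, b - delta + tol_b]
    lo = np.searchsorted(mz, mz - t.delta_mass - tol, side="left")
    hi = np.searchsorted(mz, mz - t.delta_mass + tol, side="right")
    return int(np.sum(hi - lo))


def transformation_profile(peaks: PeakList,
                           transformations: list[Transformation] = [OXYGEN, CARBON],
                           tol_ppm: float = 1.0,
                           tol_da: float | None = None) -> TransformationCounts:
    """Pair counts per transformation plus the O:C ratio.

    The ratio is count("O") / count("C"); a zero carbon count makes it
    missing (NaN) with a diagnostic, never infinite.
    """
    if not transformations:
        raise ValueError("transformation list must be nonempty")
    counts = {t.name: count_mass_differences(peaks, t, tol_ppm=tol_ppm, tol_da=tol_da)
              for t in transformations}
    n_o, n_c = counts.get("O", 0), counts.get("C", 0)
    if n_c == 0:
        if n_o:
            logger.warning("sample %s: zero C-difference pairs; O:C ratio undefined",
                           peaks.sample_id)
        ratio = 0.0 if n_o == 0 else float("nan")
    else:
        ratio = n_o / n_c
    return TransformationCounts(sample_id=peaks.sample_id, counts=counts, o_to_c_ratio=ratio)


def depth_profile(profiles: list[TransformationCounts],
                  samples: pd.DataFrame) -> pd.DataFrame:
    """Long table (station, depth, transformation, count, ratio), by station then depth.

    ``samples`` needs columns sample_id, station, depth_m; every profile's
    sample must resolve.  The result is independent of input order.
    """
    meta = samples.set_index("sample_id")
    rows = []
    for prof in profiles:
        if prof.sample_id not in meta.index:
            raise ValueError(f"unknown sample id {prof.sample_id!r}")
        st = meta.loc[prof.sample_id, "station"]
        dm = float(meta.loc[prof.sample_id, "depth_m"])
        for name, count in sorted(prof.counts.items()):
            rows.append(dict(station=st, depth_m=dm, sample_id=prof.sample_id,
                             transformation=name, count=count, ratio=prof.o_to_c_ratio))
    df = pd.DataFrame(rows, columns=["station", "depth_m", "sample_id",
                                     "transformation", "count", "ratio"])
    return (df.sort_values(["station", "depth_m", "transformation"], kind="mergesort")
            .reset_index(drop=True))


def read_peaklist_csv(path, sample_id: str, depth: float, station: str = "") -> PeakList:
    """Load a one-column (``mz``) CSV peak list; extra columns (intensity) are ignored."""
    df = pd.read_csv(path)
    if "mz" not in df.columns:
        raise ValueError(f"{path}: peak list CSV needs an 'mz' column")
    return PeakList(sample_id=sample_id, depth=depth, station=station,
                    mz=df["mz"].to_numpy(dtype=float))
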