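"""Region profiles and the correlation-based heterogeneity score.

Each partition is summarized by the arithmetic mean of its member tiles'
scaled feature rows (its "region profile").  Morphologic similarity between
two regions is the Pearson correlation r of their profiles computed across
the d features; lower r means greater heterogeneity.  On a human-calibrated
scale, tumor-versus-normal comparisons average r = 0.35, and tumor-tumor
pairs average r = 0.55 when the difference is obvious at low power
("severe"), 0.75 when visible only at high power ("moderate"), and 0.84 when
subtle even at high power ("mild").  :func:`categorize_r` maps an r value
onto that scale using midpoint cutpoints between the category means — a
documented convention, since only the means and the moderate/severe boundary
(r < 0.74) are anchored; the cutpoints are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from .partition import PartitionMap

__all__ = [
    "RegionProfile",
    "HeterogeneityMatrix",
    "region_profiles",
    "pairwise_r",
    "categorize_r",
    "DEFAULT_CUTPOINTS",
]

#: midpoints of the calibrated category means (0.35 / 0.55 / 0.75 / 0.84)
DEFAULT_CUTPOINTS = (0.45, 0.65, 0.795)

CATEGORIES = ("lesional_vs_nonlesional", "severe", "moderate", "mild")


@dataclass
class RegionProfile:
    """One partition's identity, size and mean scaled feature vector."""

    region_id: tuple[str, int]  # (slide_id, label)
    n_tiles: int
    mean_vector: np.ndarray = field(repr=False)
    annotation: str | None = None

    def __post_init__(self) -> None:
        self.mean_vector = np.asarray(self.mean_vector, dtype=np.float64)
        if self.n_tiles < 1:
            raise ValueError("region must contain at least one tile")
        if not np.all(np.isfinite(self.mean_vector)):
            raise ValueError("mean vector must be finite")


@dataclass
class HeterogeneityMatrix:
    region_ids: list[tuple[str, int]]
    r: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        m = len(self.region_ids)
        if self.r.shape != (m, m):
            raise ValueError("r must be m x m")

    def to_frame(self):
        import pandas as pd

        names = [f"{s}:{lab}" for s, lab in self.region_ids]
        return pd.DataFrame(self.r, index=names, columns=names)


def region_profiles(fm: FeatureMatrix, pm: PartitionMap) -> list[RegionProfile]:
    """Mean scaled feature vector of every non-empty partition label."""
    if not fm.scaled:
        raise RuntimeError("feature matrix must be scaled")
    labels = pm.labels_for(fm.tile_ids)
    profiles = []
    for lab in range(1, pm.k + 1):
        mask = labels == lab
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"label {lab} has no tiles; skipped", stacklevel=2)
            continue
        profiles.append(
            RegionProfile(
                region_id=(fm.slide_id, lab),
                n_tiles=n,
                mean_vector=fm.values[mask].mean(axis=0),
            )
        )
    return profiles


def pairwise_r(profiles: list[RegionProfile]) -> HeterogeneityMatrix:
    """Pearson correlation (across the d features) between all profile pairs.

    The diagonal is fixed at 1.  Profiles with a constant mean vector have
    undefined correlations; those entries are reported as NaN with a warning
    rather than coerced to 0.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 region profiles")
    d = profiles[0].mean_vector.shape[0]
    if d < 3:
        raise ValueError("profiles must have at least 3 features")
    if any(p.mean_vector.shape[0] != d for p in profiles):
        raise ValueError("all profiles must share the same feature dimension")
    M = np.vstack([p.mean_vector for p in profiles])
    constant = M.std(axis=1) == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(M)
    r = np.clip(r, -1.0, 1.0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} region profile(s) constant; "
            "their correlations are undefined (NaN)",
            stacklevel=2,
        )
        r[constant, :] = np.nan
        r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    return HeterogeneityMatrix([p.region_id for p in profiles], r)


def categorize_r(
    r_value: float, cutpoints: tuple[float, float, float] = DEFAULT_CUTPOINTS
) -> str:
    """Map a heterogeneity score r onto the semiquantitative category scale.

    ``r < cut[0]`` -> 'lesional_vs_nonlesional' (tumor-vs-normal-like);
    ``cut[0] <= r < cut[1]`` -> 'severe'; ``cut[1] <= r < cut[2]`` ->
    'moderate'; ``r >= cut[2]`` -> 'mild'.  An approximation of a
    human-calibrated scale, not a measurement.
    """
    if not -1.0 <= r_value <= 1.0:
        raise ValueError(f"r must lie in [-1, 1], got {r_value}")
    c0, c1, c2 = cutpoints
    if not c0 < c1 < c2:
        raise ValueError("cutpoints must be strictly increasing")
    if r_value < c0:
        return "lesional_vs_nonlesional"
    if r_value < c1:
        return "severe"
    if r_value < c2:
        return "moderate"
    return "mild"
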