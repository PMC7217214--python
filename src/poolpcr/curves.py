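"""Amplification-curve feature extraction and inverse diversity/concentration
estimation.

An amplification trajectory is reduced to a small feature vector — threshold
cycle (Ct), peak location and height, endpoint, and the peak-to-endpoint
decline ratio — and classified as sigmoidal (classic qPCR), peaked (high
diversity: fluorescence collapses after primer exhaustion as reshuffled
mismatched pairs dominate), or intermediate.  Estimation inverts the forward
model by nearest-neighbor matching in standardized feature space against a
simulated calibration bank over a (diversity, concentration) grid.  The
quantitative estimator is an operationalization built on the forward model;
the underlying readout only promises that curves shift with concentration
and reshape with diversity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .library import LibrarySpec
from .simulate import SimConfig, Trajectory, simulate

__all__ = [
    "CurveFeatures",
    "CalibrationBank",
    "EstimateResult",
    "extract_features",
    "build_bank",
    "estimate",
    "temperature_contrast",
]

SHAPE_SIGMOIDAL = "sigmoidal"
SHAPE_INTERMEDIATE = "intermediate"
SHAPE_PEAKED = "peaked"

# decline-ratio cutpoints for shape classes; arbitrary but fixed
_DECLINE_SIGMOIDAL = 0.1
_DECLINE_PEAKED = 0.5

_FEATURE_COLUMNS = ("ct", "endpoint", "decline_ratio")


@dataclass(frozen=True)
class CurveFeatures:
    """Scalar summary of one amplification trajectory."""

    ct: float | None
    peak_cycle: int | None
    peak_height: float
    endpoint: float
    decline_ratio: float
    shape_class: str
    threshold_crossed: bool


@dataclass(frozen=True)
class EstimateResult:
    diversity: int
    concentration: float
    distance: float
    extrapolated: bool


@dataclass
class CalibrationBank:
    """Simulated features over a (diversity, concentration) grid."""

    frame: pd.DataFrame
    fingerprint: str

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# poolpcr calibration bank\n# fingerprint={self.fingerprint}\n")
            self.frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationBank":
        fingerprint = ""
        with open(path) as fh:
            for line in fh:
                if line.startswith("# fingerprint="):
                    fingerprint = line.strip().split("=", 1)[1]
                if not line.startswith("#"):
                    break
        frame = pd.read_csv(path, comment="#")
        return cls(frame, fingerprint)


def extract_features(traj: Trajectory, threshold: float = 0.1) -> CurveFeatures:
    """Reduce a trajectory to Ct, peak, endpoint and shape class.

    Ct is the fractional cycle of the first upward threshold crossing
    (linear interpolation); it is ``None`` — with ``threshold_crossed``
    False — if the curve never reaches the threshold.  The default threshold
    of 0.1 is relative to the diversity-1 reference plateau.
    """
    fluor = np.asarray(traj.fluorescence, dtype=float)
    cycles = np.asarray(traj.cycle, dtype=float)
    if fluor.size == 0:
        raise ValueError("empty trajectory")
    ct: float | None = None
    crossed = False
    if fluor[0] >= threshold:
        ct, crossed = float(cycles[0]), True
    else:
        above = np.nonzero(fluor >= threshold)[0]
        if above.size:
            i = above[0]
            frac = (threshold - fluor[i - 1]) / (fluor[i] - fluor[i - 1])
            ct = float(cycles[i - 1] + frac * (cycles[i] - cycles[i - 1]))
            crossed = True
    i_peak = int(np.argmax(fluor))
    peak_height = float(fluor[i_peak])
    endpoint = float(fluor[-1])
    decline = (peak_height - endpoint) / peak_height if peak_height > 0 else 0.0
    decline = float(min(max(decline, 0.0), 1.0))
    if decline < _DECLINE_SIGMOIDAL:
        shape = SHAPE_SIGMOIDAL
    elif decline <= _DECLINE_PEAKED:
        shape = SHAPE_INTERMEDIATE
    else:
        shape = SHAPE_PEAKED
    peak_cycle = int(cycles[i_peak]) if i_peak < fluor.size - 1 else None
    return CurveFeatures(ct, peak_cycle, peak_height, endpoint, decline, shape, crossed)


def _ladder_spec(n_degenerate: int, total: int = 20) -> LibrarySpec:
    from .fixtures import x_n  # local import to avoid a cycle

    return x_n(n_degenerate, total)


def build_bank(
    degenerate_lengths: Sequence[int],
    concentrations: Sequence[float],
    config: SimConfig | None = None,
    threshold: float = 0.1,
) -> CalibrationBank:
    """Simulate features for every (diversity = 4^n, concentration) grid point.

    Deterministic per grid point; the fingerprint hashes the grid and the
    run conditions so a cached bank can be matched to its config.
    """
    if not degenerate_lengths or not concentrations:
        raise ValueError("grids must be non-empty")
    if config is None:
        config = SimConfig()
    rows = []
    for n in degenerate_lengths:
        spec = _ladder_spec(n)
        for conc in concentrations:
            traj = simulate(spec, replace(config, initial_template_conc=conc))
            feats = extract_features(traj, threshold)
            rows.append(
                {
                    "n_degenerate": n,
                    "diversity": 4**n,
                    "concentration": conc,
                    "ct": feats.ct,
                    "endpoint": feats.endpoint,
                    "decline_ratio": feats.decline_ratio,
                    "shape_class": feats.shape_class,
                }
            )
    frame = pd.DataFrame(rows)
    payload = json.dumps(
        {
            "lengths": list(map(int, degenerate_lengths)),
            "concentrations": [float(c) for c in concentrations],
            "config": repr(config),
            "threshold": threshold,
        },
        sort_keys=True,
    )
    fingerprint = hashlib.sha1(payload.encode()).hexdigest()[:16]
    return CalibrationBank(frame, fingerprint)


def estimate(features: CurveFeatures, bank: CalibrationBank) -> EstimateResult:
    """Nearest calibration point in standardized (Ct, endpoint, decline) space.

    Features are z-scored by bank-wide statistics before the Euclidean
    match; exact ties break toward the lower diversity.  ``extrapolated``
    flags a query outside the bank's feature hull.
    """
    if features.ct is None:
        raise ValueError("query curve never crossed the threshold; cannot estimate")
    frame = bank.frame
    query = np.array([features.ct, features.endpoint, features.decline_ratio])
    values = frame[list(_FEATURE_COLUMNS)].to_numpy(dtype=float)
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    std[std == 0] = 1.0
    dist = np.sqrt((((values - mean) / std - (query - mean) / std) ** 2).sum(axis=1))
    order = np.lexsort((frame["diversity"].to_numpy(), np.round(dist, 12)))
    best = order[0]
    extrapolated = bool(
        np.any(query < values.min(axis=0) - 1e-12)
        or np.any(query > values.max(axis=0) + 1e-12)
    )
    return EstimateResult(
        diversity=int(frame["diversity"].iloc[best]),
        concentration=float(frame["concentration"].iloc[best]),
        distance=float(dist[best]),
        extrapolated=extrapolated,
    )


def temperature_contrast(
    libraries: Sequence[LibrarySpec],
    temps: Sequence[float],
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Mean pairwise trajectory distance of a library panel per elongation
    temperature.

    The contrast is the mean over library pairs of the mean per-cycle
    absolute fluorescence difference; raising the elongation temperature
    spreads low-diversity curves apart, lowering it spreads high-diversity
    curves.
    """
    if len(temps) < 2:
        raise ValueError("need at least two temperatures")
    if config is None:
        config = SimConfig()
    rows = []
    for t in temps:
        thermal = replace(config.thermal, t_elongation=t)
        trajs = [
            simulate(spec, replace(config, thermal=thermal)) for spec in libraries
        ]
        distances = [
            float(np.mean(np.abs(a.fluorescence - b.fluorescence)))
            for i, a in enumerate(trajs)
            for b in trajs[i + 1 :]
        ]
        rows.append(
            {
                "temperature": float(t),
                "mean_pairwise_distance": float(np.mean(distances)) if distances else 0.0,
            }
        )
    return pd.DataFrame(rows)
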