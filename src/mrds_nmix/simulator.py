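"""Synthetic two-observer distance-sampling surveys of grouped animals.

The generative model: group centres fall uniformly in ``[0, w)``
perpendicular distance from the transect; group sizes are zero-truncated
Poisson; each of two independent observers detects a group with
probability ``p0 * exp(-d^2 / (2 sigma^2))`` where the half-normal scale
depends on group size through ``log sigma = beta0 + beta1 log n``; and
each detecting observer records a zero-truncated binomial count of the
group, with per-individual detection ``r0 * exp(-d^2 / (2 tau^2))``.
Groups missed by both observers never enter the survey dataset.

Distances are recorded without measurement error, and both detections
and counts are conditionally independent between observers given the
group's distance and size ("full independence").
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import (
    ZTBinomialParams,
    ZTPoissonParams,
    halfnormal_kernel,
    ztbinom_sample,
    ztpois_sample,
)

__all__ = [
    "Scenario",
    "TrueState",
    "SurveyDataset",
    "simulate_dataset",
    "scenario_table",
]

#: Sentinel for "observer did not detect the group, so no count exists".
#: Zero is impossible under zero truncation, but -1 is used to keep the
#: sentinel unmistakable; CSV round-trips write an empty field instead.
MISSING_COUNT = -1

SURVEY_COLUMNS = ["group_id", "y1", "y2", "distance", "count1", "count2"]


@dataclass(frozen=True)
class Scenario:
    """One simulation setting: generative parameters plus design constants.

    Parameters
    ----------
    lam : mean group size (zero-truncated Poisson rate).
    beta0, beta1 : log-scale intercept and group-size effect of the
        half-normal group-detection scale, ``log sigma = beta0 + beta1 log n``.
    tau : half-normal scale (m) of the per-individual detection decay.
    p0 : probability of detecting a group on the transect line.
    r0 : probability of counting an individual on the transect line.
    n_groups : groups available for detection in the strip.
    strip_width : perpendicular truncation distance w (m).
    n_observers : independent observers (the model requires two).
    """

    lam: float
    beta0: float
    beta1: float
    tau: float
    p0: float
    r0: float
    n_groups: int = 200
    strip_width: float = 100.0
    n_observers: int = 2
    scenario_id: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p0 <= 1:
            raise ValueError(f"p0 must be in (0, 1], got {self.p0}")
        if not 0 < self.r0 <= 1:
            raise ValueError(f"r0 must be in (0, 1], got {self.r0}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.strip_width <= 0:
            raise ValueError(f"strip_width must be positive, got {self.strip_width}")
        if self.n_groups < 1:
            raise ValueError(f"n_groups must be >= 1, got {self.n_groups}")
        if self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")

    def sigma(self, n) -> np.ndarray:
        """Group-detection half-normal scale for group size ``n``."""
        return np.exp(self.beta0 + self.beta1 * np.log(np.asarray(n, dtype=float)))


@dataclass(frozen=True)
class TrueState:
    """Latent truth for every simulated group, detected or not.

    ``counts[i, j]`` is ``MISSING_COUNT`` where observer ``j`` did not
    detect group ``i`` (no count is generated for undetected groups).
    """

    distances: np.ndarray  # (n_groups,) float, in [0, w)
    sizes: np.ndarray  # (n_groups,) int >= 1
    detections: np.ndarray  # (n_groups, n_observers) in {0, 1}
    counts: np.ndarray  # (n_groups, n_observers) int, MISSING_COUNT sentinel

    @property
    def n_total(self) -> int:
        """True total abundance: the sum of all group sizes."""
        return int(self.sizes.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "group_id": np.arange(len(self.sizes)),
                "distance": self.distances,
                "size": self.sizes,
            }
        )
        for j in range(self.detections.shape[1]):
            df[f"y{j + 1}"] = self.detections[:, j]
            df[f"count{j + 1}"] = self.counts[:, j]
        return df


@dataclass
class SurveyDataset:
    """The observable slice of a survey: one row per detected group.

    Backed by a DataFrame with columns ``group_id, y1, y2, distance,
    count1, count2``; counts are ``MISSING_COUNT`` where the observer did
    not detect the group (written as an empty field in CSV).
    """

    table: pd.DataFrame
    strip_width: float
    n_observers: int = 2

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SURVEY_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"survey table missing columns {missing}")
        y = t[["y1", "y2"]].to_numpy()
        if len(t) and not np.all(y.sum(axis=1) >= 1):
            raise ValueError("every survey row must have at least one detection")
        for j in (1, 2):
            cj = t[f"count{j}"].to_numpy()
            det = t[f"y{j}"].to_numpy() == 1
            if np.any(cj[det] < 1):
                raise ValueError("counts from detecting observers must be >= 1")
            if np.any(cj[~det] != MISSING_COUNT):
                raise ValueError("counts must be missing where the observer did not detect")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def distances(self) -> np.ndarray:
        return self.table["distance"].to_numpy(dtype=float)

    @property
    def detections(self) -> np.ndarray:
        return self.table[["y1", "y2"]].to_numpy(dtype=np.int64)

    @property
    def counts(self) -> np.ndarray:
        """(n, 2) counts with ``MISSING_COUNT`` where undetected."""
        return self.table[["count1", "count2"]].to_numpy(dtype=np.int64)

    @property
    def max_counts(self) -> np.ndarray:
        """Per-row maximum available count (the field-recorded group size)."""
        return self.counts.max(axis=1)

    def to_csv(self, path_or_buf) -> None:
        out = self.table.copy()
        for c in ("count1", "count2"):
            out[c] = out[c].astype("Int64").where(out[c] != MISSING_COUNT, pd.NA)
        out.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, strip_width: float) -> "SurveyDataset":
        df = pd.read_csv(path_or_buf)
        for c in ("count1", "count2"):
            df[c] = df[c].fillna(MISSING_COUNT).astype(np.int64)
        for c in ("group_id", "y1", "y2"):
            df[c] = df[c].astype(np.int64)
        return cls(table=df[SURVEY_COLUMNS], strip_width=strip_width)

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def simulate_dataset(
    scn: Scenario, rng: np.random.Generator
) -> tuple[SurveyDataset, TrueState]:
    """Simulate one survey under the grouped-animal generative model.

    Returns the observable dataset (detected groups only) together with
    the full latent truth used to generate it.
    """
    n, j_obs = scn.n_groups, scn.n_observers
    d = rng.uniform(0.0, scn.strip_width, size=n)
    sizes = ztpois_sample(ZTPoissonParams(scn.lam), rng, size=n)
    sigma = scn.sigma(sizes)
    p = scn.p0 * halfnormal_kernel(d, sigma)
    y = (rng.random((n, j_obs)) < p[:, None]).astype(np.int64)
    r = scn.r0 * halfnormal_kernel(d, scn.tau)

    counts = np.full((n, j_obs), MISSING_COUNT, dtype=np.int64)
    for i in range(n):
        for j in range(j_obs):
            if y[i, j] == 1:
                counts[i, j] = ztbinom_sample(
                    ZTBinomialParams(min(r[i], 1.0), int(sizes[i])), rng
                )

    truth = TrueState(distances=d, sizes=sizes, detections=y, counts=counts)

    seen = y.sum(axis=1) >= 1
    table = pd.DataFrame(
        {
            "group_id": np.arange(n)[seen],
            "y1": y[seen, 0],
            "y2": y[seen, 1],
            "distance": d[seen],
            "count1": counts[seen, 0],
            "count2": counts[seen, 1],
        }
    ).reset_index(drop=True)
    data = SurveyDataset(table=table, strip_width=scn.strip_width, n_observers=j_obs)
    return data, truth


# The 12 study settings: (lam, exp(beta0), beta1, tau, p0, r0).  beta0 is
# stored as the log of the tabulated scale.
_SCENARIO_ROWS = [
    (1, 1.0, 65.0, 0.25, 80.0, 1.0, 1.0),
    (2, 1.0, 35.0, 0.25, 40.0, 1.0, 1.0),
    (3, 1.0, 65.0, 0.25, 80.0, 0.8, 1.0),
    (4, 1.0, 45.0, 0.75, 80.0, 0.8, 1.0),
    (5, 4.0, 45.0, 0.25, 80.0, 1.0, 1.0),
    (6, 4.0, 25.0, 0.25, 40.0, 1.0, 1.0),
    (7, 4.0, 60.0, 0.25, 80.0, 0.8, 0.9),
    (8, 4.0, 20.0, 0.75, 80.0, 0.8, 0.9),
    (9, 20.0, 20.0, 0.35, 80.0, 1.0, 1.0),
    (10, 20.0, 13.0, 0.35, 50.0, 1.0, 1.0),
    (11, 20.0, 25.0, 0.35, 80.0, 0.8, 0.9),
    (12, 20.0, 8.0, 0.75, 80.0, 0.8, 0.9),
]


def scenario_table() -> list[Scenario]:
    """The 12 simulation scenarios of the study design.

    All share 200 groups available for detection and a 100 m strip width;
    they vary mean group size, the detection-scale intercept and
    group-size effect, the individual-detection scale, and the on-transect
    detection probabilities of groups and individuals.
    """
    return [
        Scenario(
            lam=lam,
            beta0=float(np.log(scale)),
            beta1=beta1,
            tau=tau,
            p0=p0,
            r0=r0,
            n_groups=200,
            strip_width=100.0,
            scenario_id=sid,
        )
        for sid, lam, scale, beta1, tau, p0, r0 in _SCENARIO_ROWS
    ]
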