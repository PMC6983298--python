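"""Data model, table readers/writers and configuration.

All tables are plain CSV with a documented header contract.  Units are
kilometres for distances and effort, km^2 for areas, groups km^-2 and
individuals km^-2 for densities.

Cell table (one row per spatio-temporal analysis unit)
    required columns: cell_id, platform (ship|aerial), period_id, effort_km,
    trunc_W_km, searched_area_km2, cell_area_km2, n_groups;
    columns prefixed ``det_`` are detection-condition covariates (Beaufort,
    glare, ...); all remaining columns are habitat covariates.

Sighting table (one row per detected group)
    required columns: sight_id, cell_id, platform, distance_km, obs1, obs2
    (0/1 capture-history indicators), group_size; ``det_`` columns as above.
    Sightings beyond the platform truncation distance are removed, with the
    removal count logged; all other violations abort the read (fail-fast).

Prediction-grid table
    cell_id, cell_area_km2, plus the habitat covariates of the fitted model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .smooths import SmoothSpec

__all__ = [
    "CellRecord", "SightingRecord", "StudyConfig",
    "SchemaError", "ValidationError",
    "read_cell_table", "read_sighting_table", "read_grid_table",
    "write_cell_table", "write_sighting_table",
    "write_draws", "read_draws",
]

logger = logging.getLogger("hierdsm")

PLATFORMS = ("ship", "aerial")
_CELL_REQUIRED = ["cell_id", "platform", "period_id", "effort_km", "trunc_W_km",
                  "searched_area_km2", "cell_area_km2", "n_groups"]
_SIGHT_REQUIRED = ["sight_id", "cell_id", "platform", "distance_km",
                   "obs1", "obs2", "group_size"]
_DET_PREFIX = "det_"


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """A row violates a documented invariant."""


@dataclass
class CellRecord:
    """One spatio-temporal analysis unit (grid cell x 8-day period)."""

    cell_id: str
    platform: str
    period_id: str
    effort_km: float
    trunc_W_km: float
    searched_area_km2: float
    cell_area_km2: float
    n_groups: float
    habitat_covs: dict = field(default_factory=dict)
    detect_covs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise ValidationError(f"cell {self.cell_id}: unknown platform {self.platform!r}")
        if self.effort_km < 0 or self.n_groups < 0:
            raise ValidationError(f"cell {self.cell_id}: negative effort or count")
        if self.trunc_W_km <= 0 or self.cell_area_km2 <= 0 or self.searched_area_km2 < 0:
            raise ValidationError(f"cell {self.cell_id}: non-positive truncation or area")
        if self.effort_km == 0 and self.n_groups > 0:
            raise ValidationError(
                f"cell {self.cell_id}: {self.n_groups} groups recorded with zero effort")
        vals = list(self.habitat_covs.values()) + list(self.detect_covs.values())
        if not np.all(np.isfinite(vals)) if vals else False:
            raise ValidationError(f"cell {self.cell_id}: non-finite covariate value")
        if self.searched_area_km2 > self.cell_area_km2:
            logger.warning("cell %s: searched area %.3g exceeds cell area %.3g "
                           "(transects may cross cells)", self.cell_id,
                           self.searched_area_km2, self.cell_area_km2)


@dataclass
class SightingRecord:
    """One detected group with its distance, capture history and size."""

    sight_id: str
    cell_id: str
    platform: str
    distance_km: float
    capture: tuple
    group_size: int
    detect_covs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise ValidationError(f"sighting {self.sight_id}: unknown platform {self.platform!r}")
        w1, w2 = self.capture
        if (w1, w2) not in ((0, 1), (1, 0), (1, 1)):
            raise ValidationError(
                f"sighting {self.sight_id}: capture history {(w1, w2)} invalid "
                "(undetected groups cannot appear)")
        if self.distance_km < 0:
            raise ValidationError(f"sighting {self.sight_id}: negative distance")
        if self.group_size < 1:
            raise ValidationError(f"sighting {self.sight_id}: group size must be >= 1")


@dataclass
class StudyConfig:
    """Model structure, priors and MCMC settings."""

    smooths: list = field(default_factory=list)          # SmoothSpec per covariate
    key_ship: str = "half_normal"
    key_aerial: str = "half_normal"
    truncation: dict = field(default_factory=lambda: {"ship": 6.0, "aerial": 0.9})
    detect_cov_names: list = field(default_factory=list)
    # MCMC
    n_chains: int = 2
    n_iter: int = 50_000
    n_burn: int = 20_000
    thin: int = 50
    seed: int = 1
    # informative beta priors (availability; externally estimated aerial g(0))
    availability_mean: float = 0.37
    availability_cv: float = 0.34
    g0_aerial_mean: float = 0.67
    g0_aerial_cv: float = 0.16
    # likelihood structure
    offset_mode: str = "poisson"       # where log(p A) enters the CPG
    phi_mode: str = "all"              # split coefficients on all columns / intercept only
    fix_components: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_iter <= self.n_burn:
            raise ValueError("n_iter must exceed n_burn")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")
        for m, c in ((self.availability_mean, self.availability_cv),
                     (self.g0_aerial_mean, self.g0_aerial_cv)):
            if not (0.0 < m < 1.0) or c <= 0:
                raise ValueError("prior means must be in (0,1) with positive CV")
        if self.offset_mode not in ("poisson", "split"):
            raise ValueError("offset_mode must be 'poisson' or 'split'")
        if self.phi_mode not in ("intercept", "all"):
            raise ValueError("phi_mode must be 'intercept' or 'all'")
        self.smooths = [s if isinstance(s, SmoothSpec) else SmoothSpec(**s)
                        for s in self.smooths]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["smooths"] = [asdict(s) if isinstance(s, SmoothSpec) else s
                        for s in self.smooths]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _require(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column {c!r}")


def _split_covs(row: Mapping, known: set) -> tuple[dict, dict]:
    hab, det = {}, {}
    for k, v in row.items():
        if k in known:
            continue
        if k.startswith(_DET_PREFIX):
            det[k[len(_DET_PREFIX):]] = float(v)
        else:
            hab[k] = float(v)
    return hab, det


def read_cell_table(path, config: StudyConfig | None = None) -> list:
    """Read and validate the cell table; rows ordered by (cell_id, period_id)."""
    df = pd.read_csv(path)
    _require(df, _CELL_REQUIRED, path)
    df = df.sort_values(["cell_id", "period_id"], kind="stable").reset_index(drop=True)
    known = set(_CELL_REQUIRED)
    records = []
    for i, row in enumerate(df.to_dict("records")):
        hab, det = _split_covs(row, known)
        try:
            records.append(CellRecord(
                cell_id=str(row["cell_id"]), platform=str(row["platform"]),
                period_id=str(row["period_id"]), effort_km=float(row["effort_km"]),
                trunc_W_km=float(row["trunc_W_km"]),
                searched_area_km2=float(row["searched_area_km2"]),
                cell_area_km2=float(row["cell_area_km2"]),
                n_groups=float(row["n_groups"]),
                habitat_covs=hab, detect_covs=det))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return records


def read_sighting_table(path, config: StudyConfig) -> list:
    """Read, validate and truncate the sighting table.

    Sightings with distance beyond the platform truncation distance are
    removed (a documented filter, logged); any other violation aborts.
    """
    df = pd.read_csv(path)
    _require(df, _SIGHT_REQUIRED, path)
    known = set(_SIGHT_REQUIRED)
    records, n_truncated = [], 0
    for i, row in enumerate(df.to_dict("records")):
        platform = str(row["platform"])
        W = config.truncation.get(platform)
        if W is None:
            raise ValidationError(f"{path} row {i}: no truncation distance for {platform!r}")
        _, det = _split_covs(row, known)
        try:
            rec = SightingRecord(
                sight_id=str(row["sight_id"]), cell_id=str(row["cell_id"]),
                platform=platform, distance_km=float(row["distance_km"]),
                capture=(int(row["obs1"]), int(row["obs2"])),
                group_size=int(row["group_size"]), detect_covs=det)
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
        if rec.distance_km > W:
            n_truncated += 1
            continue
        records.append(rec)
    if n_truncated:
        logger.info("%s: removed %d sightings beyond truncation distance",
                    path, n_truncated)
    return records


def read_grid_table(path) -> pd.DataFrame:
    """Read the prediction grid (cell_id, cell_area_km2, habitat covariates)."""
    df = pd.read_csv(path)
    _require(df, ["cell_id", "cell_area_km2"], path)
    return df


def write_cell_table(records, path) -> None:
    rows = []
    for r in records:
        row = {k: getattr(r, k) for k in _CELL_REQUIRED}
        row.update(r.habitat_covs)
        row.update({_DET_PREFIX + k: v for k, v in r.detect_covs.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_sighting_table(records, path) -> None:
    rows = []
    for r in records:
        row = {"sight_id": r.sight_id, "cell_id": r.cell_id, "platform": r.platform,
               "distance_km": r.distance_km, "obs1": r.capture[0],
               "obs2": r.capture[1], "group_size": r.group_size}
        row.update({_DET_PREFIX + k: v for k, v in r.detect_covs.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# posterior draw files

def write_draws(draws, path) -> None:
    """Write retained MCMC draws as columnar CSV (chain, iteration first)."""
    names = list(draws.names)
    if len(set(names)) != len(names):
        raise ValueError("parameter-name collision in draw store")
    n_chains, n_draws = draws.shape
    if n_draws == 0 or n_chains == 0:
        raise ValueError("cannot write an empty draw store")
    cols = {
        "chain": np.repeat(np.arange(n_chains), n_draws),
        "iteration": np.tile(np.arange(n_draws), n_chains),
    }
    for name in names:
        cols[name] = draws.get(name).reshape(-1)
    # default float formatting is shortest-round-trip repr; exact on read-back
    pd.DataFrame(cols).to_csv(path, index=False)


def read_draws(path):
    """Read a draw file written by :func:`write_draws` back into PosteriorDraws."""
    from .hier_model import PosteriorDraws

    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("chain", "iteration"):
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column {c!r}")
    chains = np.sort(df["chain"].unique())
    names = [c for c in df.columns if c not in ("chain", "iteration")]
    per_chain = []
    for ch in chains:
        sub = df[df["chain"] == ch].sort_values("iteration")
        per_chain.append(sub[names].to_numpy(dtype=float))
    arr = np.stack(per_chain)  # (n_chains, n_draws, n_params)
    return PosteriorDraws(
        names=names,
        values={nm: arr[:, :, i] for i, nm in enumerate(names)},
        meta={"n_chains": len(chains)},
    )
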