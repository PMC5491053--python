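"""Loading and preprocessing of the entity-by-measure quality matrix.

The pipeline consumes a numeric matrix of entities (hospitals) by quality
measures, with missing cells, together with per-measure metadata (the quality
domain each measure belongs to, and whether higher or lower raw values denote
better care).  Preprocessing filters out poorly reported rows and columns
(90% completeness on each axis by default), orients every measure so that
positive means better, z-scores each measure, winsorizes at +/-4 SD, and
fills the small residue of missing cells with the column mean (0 on the
standardized scale).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig

__all__ = [
    "QualityMatrix",
    "load_matrix",
    "filter_completeness",
    "orient_measures",
    "standardize",
    "clip_extremes",
    "impute_missing",
    "preprocess",
]

DOMAINS = (
    "process",
    "experience",
    "value",
    "safety",
    "surgery",
    "readmission",
    "mortality",
)
DIRECTIONS = ("higher_better", "lower_better")


@dataclass(frozen=True)
class QualityMatrix:
    """An entity-by-measure matrix with a missingness mask and measure metadata.

    ``values`` is dense float; cells where ``observed`` is False carry no
    information (NaN until imputation).  ``meta`` is indexed by measure id with
    columns ``domain`` and ``direction``.
    """

    entity_ids: list[str]
    measure_ids: list[str]
    values: np.ndarray
    observed: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if len(self.entity_ids) != n or len(self.measure_ids) != p:
            raise ValueError("id lists do not match matrix shape")
        if self.observed.shape != (n, p):
            raise ValueError("observed mask shape mismatch")
        if len(set(self.entity_ids)) != n:
            raise ValueError("duplicate entity ids")
        if len(set(self.measure_ids)) != p:
            raise ValueError("duplicate measure ids")
        if not np.isfinite(self.values[self.observed]).all():
            raise ValueError("non-finite observed values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_completeness(self) -> np.ndarray:
        return self.observed.mean(axis=1)

    def col_completeness(self) -> np.ndarray:
        return self.observed.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[~self.observed] = np.nan
        return pd.DataFrame(vals, index=self.entity_ids, columns=self.measure_ids)


def load_matrix(path: str | Path, meta_path: str | Path) -> QualityMatrix:
    """Read the matrix CSV (first column ``entity_id``; empty cell = missing)
    and the measure-metadata CSV (``measure_id, domain, direction``)."""
    df = pd.read_csv(path, dtype={0: str})
    entity_col = df.columns[0]
    entities = df[entity_col].tolist()
    dupes = df[entity_col][df[entity_col].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate entity id(s): {sorted(set(dupes))}")
    measure_ids = [str(c) for c in df.columns[1:]]
    if len(set(measure_ids)) != len(measure_ids):
        seen: set[str] = set()
        dup = sorted({m for m in measure_ids if m in seen or seen.add(m)})
        raise ValueError(f"duplicate measure id(s): {dup}")

    raw = df.iloc[:, 1:]
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell at entity {entities[i]!r}, measure {col!r}: "
                f"{raw[col].iloc[i]!r}"
            )
        values[:, j] = parsed.to_numpy()
    observed = ~np.isnan(values)

    meta = pd.read_csv(meta_path, dtype=str).set_index("measure_id")
    missing_meta = [m for m in measure_ids if m not in meta.index]
    if missing_meta:
        raise ValueError(f"measure(s) missing from metadata: {missing_meta}")
    meta = meta.loc[measure_ids, ["domain", "direction"]]
    return QualityMatrix(entities, measure_ids, values, observed, meta)


def filter_completeness(m: QualityMatrix, cfg: PipelineConfig) -> QualityMatrix:
    """Drop entities below the row-completeness threshold, then measures below
    the column threshold (computed over the surviving entities)."""
    keep_rows = m.row_completeness() >= cfg.row_completeness_min
    if not keep_rows.any():
        raise ValueError("no entities survive filters")
    obs = m.observed[keep_rows]
    keep_cols = obs.mean(axis=0) >= cfg.col_completeness_min
    if not keep_cols.any():
        raise ValueError("no measures survive filters")
    entity_ids = [e for e, k in zip(m.entity_ids, keep_rows) if k]
    measure_ids = [s for s, k in zip(m.measure_ids, keep_cols) if k]
    return QualityMatrix(
        entity_ids,
        measure_ids,
        m.values[np.ix_(keep_rows, keep_cols)],
        m.observed[np.ix_(keep_rows, keep_cols)],
        m.meta.loc[measure_ids],
    )


def orient_measures(m: QualityMatrix) -> QualityMatrix:
    """Negate lower-is-better measures so positive always denotes better
    performance; idempotent (all directions become ``higher_better``)."""
    unknown = set(m.meta["direction"]) - set(DIRECTIONS)
    if unknown:
        raise ValueError(f"unknown direction tag(s): {sorted(unknown)}")
    flip = (m.meta["direction"] == "lower_better").to_numpy()
    values = m.values.copy()
    values[:, flip] = -values[:, flip]
    meta = m.meta.copy()
    meta["direction"] = "higher_better"
    return replace(m, values=values, meta=meta)


def standardize(m: QualityMatrix, method: str = "zscore") -> QualityMatrix:
    """Standardize each measure over its observed cells.

    ``zscore`` subtracts the mean and divides by the sample SD (n-1).
    ``rank_normal`` maps ranks through the normal quantile function (Blom
    offsets) — an alternative reading of "standardized to a normal
    distribution" for heavy-tailed measures.
    """
    values = m.values.copy()
    for j, mid in enumerate(m.measure_ids):
        obs = m.observed[:, j]
        col = values[obs, j]
        if col.size < 2:
            raise ValueError(f"measure {mid!r} has fewer than 2 observed values")
        if np.ptp(col) == 0:
            raise ValueError(f"measure {mid!r} is constant; cannot standardize")
        if method == "zscore":
            values[obs, j] = (col - col.mean()) / col.std(ddof=1)
        elif method == "rank_normal":
            ranks = stats.rankdata(col)
            values[obs, j] = stats.norm.ppf((ranks - 0.375) / (col.size + 0.25))
        else:
            raise ValueError(f"unknown standardize method {method!r}")
    return replace(m, values=values)


def clip_extremes(m: QualityMatrix, cfg: PipelineConfig) -> QualityMatrix:
    """Winsorize observed values at ``+/- cfg.clip_sd`` (no re-standardization)."""
    values = m.values.copy()
    obs = m.observed
    values[obs] = np.clip(values[obs], -cfg.clip_sd, cfg.clip_sd)
    return replace(m, values=values)


def impute_missing(m: QualityMatrix) -> QualityMatrix:
    """Fill unobserved cells with 0 — the column mean on the standardized
    scale.  The observed mask is retained for audit."""
    values = m.values.copy()
    values[~m.observed] = 0.0
    return replace(m, values=values)


def preprocess(m: QualityMatrix, cfg: PipelineConfig) -> QualityMatrix:
    """Full preprocessing chain: filter -> orient -> standardize -> clip -> impute."""
    m = filter_completeness(m, cfg)
    m = orient_measures(m)
    m = standardize(m, cfg.standardize_method)
    m = clip_extremes(m, cfg)
    return impute_missing(m)
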