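"""Domain containers and tabular I/O.

All tables are tab-separated text with a header row.  Every pipeline stage
writes its payload as a TSV plus a ``<name>.meta.json`` sidecar holding the
stage name, parameter echo, seed and timestamp, so results are diff-able and
language-neutral while remaining fully provenanced.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ARMS, StudyConfig
from .errors import SchemaError, ValidationError

GROWTH_COLUMNS = ("mouse_id", "line_id", "arm", "day", "volume_mm3")


@dataclass
class GrowthSeries:
    """One mouse's tumor-volume trajectory.

    Days are integer days post-engraftment and must be strictly increasing;
    volumes are mm^3, finite and nonnegative (0 encodes "below detection").
    """

    mouse_id: str
    line_id: str
    arm: str
    days: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.arm not in ARMS:
            raise ValidationError(
                f"arm must be one of {ARMS}, got {self.arm!r} "
                f"(mouse {self.mouse_id})"
            )
        if self.days.size == 0:
            raise ValidationError(f"empty series for mouse {self.mouse_id}")
        if self.days.size != self.volumes.size:
            raise ValidationError(
                f"days/volumes length mismatch for mouse {self.mouse_id}"
            )
        if np.any(np.diff(self.days) <= 0):
            raise ValidationError(
                f"days must be strictly increasing for mouse {self.mouse_id}"
            )
        if not np.all(np.isfinite(self.volumes)) or np.any(self.volumes < 0):
            raise ValidationError(
                f"volumes must be finite and >= 0 for mouse {self.mouse_id}"
            )

    @property
    def n_measurements(self) -> int:
        return int(self.days.size)


def read_growth_table(path: str | Path, config: StudyConfig) -> list[GrowthSeries]:
    """Parse a long-format tumor-volume TSV into one ``GrowthSeries`` per mouse.

    Required columns: ``mouse_id, line_id, arm, day, volume_mm3``.  Arm labels
    are normalized through ``config.arm_aliases``; rows are grouped by mouse
    and sorted by day.

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    ValidationError
        On non-numeric days/volumes (the offending rows are listed), duplicate
        (mouse, day) pairs, or unknown arm labels.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"growth table {path} is missing required column(s): "
            + ", ".join(missing)
        )
    for col in ("day", "volume_mm3"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()].tolist()
        if bad:
            raise ValidationError(
                f"non-numeric {col!r} values in rows {bad} of {path}"
            )
        df[col] = converted
    dupes = df.duplicated(subset=["mouse_id", "day"], keep=False)
    if dupes.any():
        pairs = df.loc[dupes, ["mouse_id", "day"]].drop_duplicates()
        raise ValidationError(
            "duplicate (mouse_id, day) measurements: "
            + "; ".join(f"{m}@{d:g}" for m, d in pairs.itertuples(index=False))
        )
    df["arm"] = [config.normalize_arm(a) for a in df["arm"]]

    series: list[GrowthSeries] = []
    for mouse_id, grp in df.groupby("mouse_id", sort=True):
        grp = grp.sort_values("day")
        arms = grp["arm"].unique()
        lines = grp["line_id"].unique()
        if len(arms) > 1 or len(lines) > 1:
            raise ValidationError(
                f"mouse {mouse_id} has inconsistent arm/line labels"
            )
        series.append(
            GrowthSeries(
                mouse_id=str(mouse_id),
                line_id=str(lines[0]),
                arm=str(arms[0]),
                days=grp["day"].to_numpy(),
                volumes=grp["volume_mm3"].to_numpy(),
            )
        )
    return series


def growth_series_to_frame(series: list[GrowthSeries]) -> pd.DataFrame:
    """Inverse of :func:`read_growth_table` (long format, one row per point)."""
    rows = []
    for s in series:
        for d, v in zip(s.days, s.volumes):
            rows.append((s.mouse_id, s.line_id, s.arm, int(d), float(v)))
    return pd.DataFrame(rows, columns=list(GROWTH_COLUMNS))


# ---------------------------------------------------------------------------
# Result bundles

@dataclass
class ResultBundle:
    """A stage result: tabular payload plus provenance.

    The payload is written as ``<out>.tsv`` (or the path given verbatim when
    it already ends in ``.tsv``) and the provenance — stage name, parameter
    echo, seed, package version, timestamp — as ``<out>.meta.json``.  The
    payload round-trips losslessly: floats are serialized with their shortest
    exact repr.
    """

    stage: str
    params: dict
    payload: pd.DataFrame
    seed: int | None = None

    def write(self, out: str | Path) -> Path:
        out = Path(out)
        tsv = out if out.suffix == ".tsv" else out.with_suffix(".tsv")
        tsv.parent.mkdir(parents=True, exist_ok=True)
        self.payload.to_csv(tsv, sep="\t", index=False)
        meta = {
            "stage": self.stage,
            "params": _jsonable(self.params),
            "seed": self.seed,
            "version": __version__,
            "written_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
        tsv.with_name(tsv.stem + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )
        return tsv


def read_bundle_payload(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bundle_meta(path: str | Path) -> dict:
    path = Path(path)
    return json.loads(path.with_name(path.stem + ".meta.json").read_text())


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
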