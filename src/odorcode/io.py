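"""Canonical tabular formats and the dataset container.

All stages of the pipeline exchange three plain CSV tables:

``spikes.csv``
    one row per spike: ``unit_id`` (string), ``time_s`` (seconds from
    recording start, non-negative, sorted within unit).
``trials.csv``
    one row per stimulus presentation: ``trial_id``, ``odorant``,
    ``concentration`` (v/v fraction; 0 for blank), ``odor_onset_s``,
    ``inhalation_onset_s`` (first inhalation after odor onset; analysis
    time zero), ``is_blank`` (0/1).
``units.csv``
    one row per isolated unit: ``unit_id``, ``region`` (``PCx`` | ``OB`` |
    ``VGAT``), ``spontaneous_rate_hz`` optional.

Times are seconds everywhere; milliseconds appear only in printed output.
Counting windows are half-open ``[start, end)``; latency peaks live on the
closed interval ``[0, 0.5]``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

BLANK_ODORANT = "mineral_oil"

#: column -> dtype for each canonical table
SPIKES_SCHEMA: Mapping[str, type] = {"unit_id": str, "time_s": float}
TRIALS_SCHEMA: Mapping[str, type] = {
    "trial_id": str,
    "odorant": str,
    "concentration": float,
    "odor_onset_s": float,
    "inhalation_onset_s": float,
    "is_blank": int,
}
UNITS_SCHEMA: Mapping[str, type] = {"unit_id": str, "region": str}
GROUND_TRUTH_SCHEMA: Mapping[str, type] = {
    "unit_id": str,
    "odorant": str,
    "label": str,
    "component": str,
    "region": str,
}


class TableValidationError(ValueError):
    """A canonical table violated its schema; names the row and column."""


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Load a CSV and validate it against ``schema``.

    Missing columns, unparseable values and basic invariant violations
    (negative times, empty identifiers) raise :class:`TableValidationError`
    naming the offending row and column.  An empty-but-headered file yields
    an empty, correctly typed frame.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in schema:
        if col not in df.columns:
            raise TableValidationError(f"{path}: missing column {col!r}")
    out = {}
    for col, typ in schema.items():
        if typ is str:
            out[col] = df[col].astype(str)
            continue
        try:
            out[col] = df[col].astype(float if typ is float else int)
        except ValueError as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else -1
            raise TableValidationError(
                f"{path}: unparseable value in column {col!r}, row {row}"
            ) from exc
    for col in df.columns:
        if col not in out:
            out[col] = df[col]
    table = pd.DataFrame(out)
    _validate(table, schema, str(path))
    return table


def _validate(table: pd.DataFrame, schema: Mapping[str, type], name: str) -> None:
    if "time_s" in table.columns and len(table):
        t = table["time_s"].to_numpy()
        if not np.all(np.isfinite(t)) or (t < 0).any():
            row = int(np.flatnonzero(~np.isfinite(t) | (t < 0))[0])
            raise TableValidationError(
                f"{name}: negative or non-finite time_s at row {row}"
            )
    if "unit_id" in table.columns and (table["unit_id"] == "").any():
        row = int(np.flatnonzero((table["unit_id"] == "").to_numpy())[0])
        raise TableValidationError(f"{name}: empty unit_id at row {row}")
    if "trial_id" in table.columns and table["trial_id"].duplicated().any():
        row = int(np.flatnonzero(table["trial_id"].duplicated().to_numpy())[0])
        raise TableValidationError(f"{name}: duplicate trial_id at row {row}")


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as CSV (no index); byte-stable for identical input."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


@dataclasses.dataclass
class Dataset:
    """Spike trains plus trial metadata — the pipeline's universal input.

    Attributes
    ----------
    units : DataFrame
        ``unit_id``, ``region`` (and any extra metadata columns).
    spikes : DataFrame
        ``unit_id``, ``time_s`` — continuous spike times per unit.
    trials : DataFrame
        one row per presentation, :data:`TRIALS_SCHEMA` columns.
    ground_truth : DataFrame or None
        per cell-odor label table (synthetic data only).
    gt_latencies : DataFrame or None
        assigned latency means per (unit, odorant, concentration).
    inhalation_onsets, exhalation_onsets : ndarray or None
        full-session breath events, if known.
    """

    units: pd.DataFrame
    spikes: pd.DataFrame
    trials: pd.DataFrame
    ground_truth: pd.DataFrame | None = None
    gt_latencies: pd.DataFrame | None = None
    inhalation_onsets: np.ndarray | None = None
    exhalation_onsets: np.ndarray | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self._trains: dict[str, np.ndarray] | None = None

    @property
    def unit_ids(self) -> list[str]:
        return list(self.units["unit_id"])

    def spike_trains(self) -> dict[str, np.ndarray]:
        """Per-unit sorted spike-time arrays (cached)."""
        if self._trains is None:
            trains = {u: np.empty(0) for u in self.unit_ids}
            for u, grp in self.spikes.groupby("unit_id", sort=False):
                trains[u] = np.sort(grp["time_s"].to_numpy())
            self._trains = trains
        return self._trains

    def subset_units(self, unit_ids: Sequence[str]) -> "Dataset":
        keep = set(unit_ids)
        units = self.units[self.units["unit_id"].isin(keep)].reset_index(drop=True)
        spikes = self.spikes[self.spikes["unit_id"].isin(keep)].reset_index(drop=True)
        ds = Dataset(units, spikes, self.trials, self.ground_truth,
                     self.gt_latencies, self.inhalation_onsets,
                     self.exhalation_onsets, dict(self.meta))
        return ds

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        paths = {
            "units": write_table(self.units, outdir / "units.csv"),
            "spikes": write_table(self.spikes, outdir / "spikes.csv"),
            "trials": write_table(self.trials, outdir / "trials.csv"),
        }
        if self.ground_truth is not None:
            paths["ground_truth"] = write_table(
                self.ground_truth, outdir / "ground_truth.csv")
        if self.gt_latencies is not None:
            paths["gt_latencies"] = write_table(
                self.gt_latencies, outdir / "gt_latencies.csv")
        if self.inhalation_onsets is not None:
            ev = pd.DataFrame({
                "onset_type": (["inhalation"] * len(self.inhalation_onsets)
                               + ["exhalation"] * len(self.exhalation_onsets)),
                "time_s": np.concatenate(
                    [self.inhalation_onsets, self.exhalation_onsets]),
            }).sort_values("time_s", kind="stable").reset_index(drop=True)
            paths["breaths"] = write_table(ev, outdir / "breaths.csv")
        return paths

    @classmethod
    def load(cls, indir: str | Path) -> "Dataset":
        indir = Path(indir)
        units = read_table(indir / "units.csv", UNITS_SCHEMA)
        spikes = read_table(indir / "spikes.csv", SPIKES_SCHEMA)
        trials = read_table(indir / "trials.csv", TRIALS_SCHEMA)
        gt = gtl = None
        if (indir / "ground_truth.csv").exists():
            gt = read_table(indir / "ground_truth.csv", GROUND_TRUTH_SCHEMA)
        if (indir / "gt_latencies.csv").exists():
            gtl = pd.read_csv(indir / "gt_latencies.csv")
        inh = exh = None
        if (indir / "breaths.csv").exists():
            ev = pd.read_csv(indir / "breaths.csv")
            inh = ev.loc[ev["onset_type"] == "inhalation", "time_s"].to_numpy()
            exh = ev.loc[ev["onset_type"] == "exhalation", "time_s"].to_numpy()
        return cls(units, spikes, trials, gt, gtl, inh, exh)


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclasses.dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, round-trippable through YAML."""

    outdir: str = "odorcode_out"
    seed: int = 0
    alpha: float = 0.05
    synth: dict = dataclasses.field(default_factory=dict)
    psth: dict = dataclasses.field(default_factory=dict)
    encoding: dict = dataclasses.field(default_factory=dict)
    decode: dict = dataclasses.field(default_factory=dict)
    mixture: dict = dataclasses.field(default_factory=dict)
    stages: list = dataclasses.field(
        default_factory=lambda: ["synth", "respiration", "metrics", "popgeom",
                                 "decode", "latmix", "slopes"])

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir: str | Path, extra: dict | None = None) -> Path:
    """Hash every file in ``outdir`` into ``manifest.json`` (determinism probe)."""
    outdir = Path(outdir)
    entries = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(outdir))] = file_sha256(p)
    manifest = {"files": entries}
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
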