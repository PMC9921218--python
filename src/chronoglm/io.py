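"""File I/O, run configuration, and quality-control filters.

Event tables follow the BIDS events.tsv convention (onset, duration,
trial_type, response_time, correct; seconds, 0-based from the first volume).
Volumes are NIfTI-1; confound tables are TSV with six motion columns and an
optional framewise-displacement (FD) column.  Subject-level QC applies the
study's exclusion rules: more than 10 missed/incorrect responses, or more
than 7.5% of volumes with FD > 0.5 mm.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import TrialTable

__all__ = [
    "RunConfig",
    "QCDecision",
    "qc_exclude_subject",
    "read_events",
    "write_events",
    "read_confounds",
    "read_nifti",
    "write_nifti",
    "write_manifest",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass
class RunConfig:
    """Pipeline configuration with every study constant as a named default."""

    # paths
    bold: str | None = None
    events: str | None = None
    confounds: str | None = None
    mask: str | None = None
    atlas: str | None = None
    # model space
    with_derivatives: bool = False
    n_folds: int = 2
    alpha0: float = 1.0
    ep_samples: int = 10_000
    seed: int = 0
    # design
    TR_s: float | None = None          # None: read from the NIfTI header
    hp_cutoff_s: float = 128.0
    # QC thresholds
    fd_mm: float = 0.5                  # framewise-displacement cutoff
    fd_frac: float = 0.075              # tolerated fraction of high-FD scans
    max_bad_trials: int = 10            # tolerated missed/incorrect responses
    min_cluster: int = 10               # minimum reported cluster size (voxels)

    def __post_init__(self) -> None:
        for name in ("fd_mm", "fd_frac", "max_bad_trials", "min_cluster"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class QCDecision:
    include: bool
    reasons: list[str] = field(default_factory=list)
    n_bad_trials: int = 0
    fd_fraction: float = 0.0


def qc_exclude_subject(
    trials: TrialTable,
    fd_series: np.ndarray | None = None,
    max_bad_trials: int = 10,
    fd_mm: float = 0.5,
    fd_frac: float = 0.075,
) -> QCDecision:
    """Apply the subject-exclusion rules (strict inequalities).

    Exclude iff the number of missed/incorrect trials exceeds
    ``max_bad_trials``, or the fraction of scans with FD above ``fd_mm``
    exceeds ``fd_frac``.  Reasons name the rule(s) that fired.
    """
    n_bad = int((~trials.correct).sum())
    reasons = []
    if n_bad > max_bad_trials:
        reasons.append("behavior")
    frac = 0.0
    if fd_series is not None:
        fd = np.asarray(fd_series, dtype=float)
        frac = float(np.mean(fd > fd_mm))
        if frac > fd_frac:
            reasons.append("motion")
    return QCDecision(include=not reasons, reasons=reasons,
                      n_bad_trials=n_bad, fd_fraction=frac)


def read_events(path: str | Path, run_duration_s: float | None = None) -> TrialTable:
    """Read a BIDS-style events.tsv into a TrialTable (with validation)."""
    df = pd.read_csv(path, sep="\t")
    try:
        trials = TrialTable.from_frame(df)
    except ValueError as err:
        raise ValueError(f"malformed events table {path}: {err}") from err
    if run_duration_s is not None and np.any(trials.onset_s > run_duration_s):
        row = int(np.argmax(trials.onset_s > run_duration_s))
        raise ValueError(
            f"events table {path}: onset at row {row} exceeds the scan "
            f"duration {run_duration_s:.1f} s")
    return trials


def write_events(trials: TrialTable, path: str | Path) -> None:
    trials.to_frame().to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_confounds(path: str | Path) -> pd.DataFrame:
    """Read a confounds TSV; requires the six motion columns, FD optional."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"confounds table {path} missing columns: {missing}")
    return df


def read_nifti(
    path: str | Path, TR_override_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Load a NIfTI volume: (data, affine, TR).

    The TR is taken from the header's fourth zoom for 4D images; a missing or
    zero header TR without an override is an error for 4D data.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    TR = TR_override_s
    if data.ndim == 4 and TR is None:
        zooms = img.header.get_zooms()
        TR = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not TR or not np.isfinite(TR):
            raise ValueError(
                f"{path}: no repetition time in the NIfTI header; pass a TR "
                "override (config TR_s)")
    return data, img.affine, TR


def write_nifti(
    data: np.ndarray, affine: np.ndarray, path: str | Path,
    TR_s: float | None = None,
) -> None:
    img = nib.Nifti1Image(np.asarray(data), affine)
    if TR_s is not None and data.ndim == 4:
        img.header.set_zooms(img.header.get_zooms()[:3] + (TR_s,))
    nib.save(img, str(path))


def write_manifest(out_dir: str | Path, config: RunConfig, inputs: dict,
                   extra: dict | None = None) -> Path:
    """Write a reproducibility manifest next to a stage's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "inputs": inputs,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
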