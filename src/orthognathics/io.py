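"""Delimited-text input/output and run configuration.

Formats (all tab-separated, '#'-prefixed metadata lines):

* landmarks:  columns ``case_id  state  name  side  x  y  z`` (mm).  Landmark
  names are matched case-insensitively against the cephalometric vocabulary,
  with the common abbreviations (UI, LI, N, S, Por, Or, Con, C, Go) accepted;
  bilateral landmarks need ``side`` = left/right.
* planning transforms: columns ``case_id  segment`` followed by the 16
  row-major entries ``m00..m33`` of the 4x4 homogeneous matrix.
* reports: per-case rows and cohort summary rows in the clinical column
  order (Translation AP, LR, UD, Pitch, Roll, Yaw).

Decimal commas ("0,26") are normalised to dots with a logged warning —
clinical exports mix both conventions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import (BILATERAL_LANDMARKS, LANDMARK_VOCABULARY,
                     CephalometricLandmarkSet, MovementReport)
from .geometry import RigidTransform

__all__ = [
    "AnalysisConfig",
    "parse_number",
    "canonical_landmark_name",
    "read_landmarks",
    "write_landmarks",
    "read_transforms",
    "write_transforms",
    "write_report",
    "read_report",
]

logger = logging.getLogger(__name__)

#: Column labels of the six components in clinical order.
REPORT_COLUMNS = {
    "d_ap": "Translation AP (mm)",
    "d_lr": "Translation LR (mm)",
    "d_ud": "Translation UD (mm)",
    "pitch": "Pitch (degree)",
    "roll": "Roll (degree)",
    "yaw": "Yaw (degree)",
}

_SYNONYMS = {
    "n": "nasion",
    "s": "sella",
    "por": "porion",
    "or": "orbitale",
    "ui": "upper_incisor",
    "li": "lower_incisor",
    "con": "condor",
    "c": "c_point",
    "cpoint": "c_point",
    "go": "gonion",
    "mc16": "mesial_cusp_16",
    "mc26": "mesial_cusp_26",
    "mc36": "mesial_cusp_36",
    "mc46": "mesial_cusp_46",
}

_DECIMAL_COMMA = re.compile(r"^-?\d+,\d+$")


def parse_number(text) -> float:
    """Parse a float, accepting a decimal comma with a logged warning."""
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        return float(text)
    s = str(text).strip()
    if _DECIMAL_COMMA.match(s):
        logger.warning("decimal comma normalised in value %r", s)
        s = s.replace(",", ".")
    return float(s)


def canonical_landmark_name(name: str, side: str | None = None) -> str:
    """Map free-form landmark spellings to the canonical vocabulary.

    Raises ``ValueError`` for unknown names, listing the vocabulary, and for
    bilateral landmarks given without a side.
    """
    key = re.sub(r"[\s\-]+", "_", str(name).strip().lower())
    key = _SYNONYMS.get(key.replace("_", ""), _SYNONYMS.get(key, key))
    side_norm = str(side).strip().lower() if side is not None else ""
    if side_norm in ("", "nan", "none", "-"):
        side_norm = ""
    elif side_norm in ("l", "left"):
        side_norm = "left"
    elif side_norm in ("r", "right"):
        side_norm = "right"
    else:
        raise ValueError(f"unknown side {side!r} for landmark {name!r}")

    if key in BILATERAL_LANDMARKS:
        if not side_norm:
            raise ValueError(
                f"landmark {name!r} is bilateral and needs side left/right")
        key = f"{key}_{side_norm}"
    elif side_norm and not key.endswith(("_left", "_right")):
        key = f"{key}_{side_norm}"
    if key not in LANDMARK_VOCABULARY:
        raise ValueError(
            f"unknown landmark {name!r} (canonical {key!r}); known landmarks: "
            + ", ".join(LANDMARK_VOCABULARY)
        )
    return key


def _read_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep, comment="#", dtype=str,
                       skip_blank_lines=True)


def read_landmarks(path: str | Path) -> dict[tuple[str, str], CephalometricLandmarkSet]:
    """Read a landmark file into one landmark set per (case_id, state)."""
    df = _read_table(path)
    required = {"case_id", "state", "name", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark file {path} lacks columns {sorted(missing)}")
    out: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for _, row in df.iterrows():
        key = (str(row["case_id"]), str(row["state"]).strip().lower())
        name = canonical_landmark_name(row["name"], row.get("side"))
        point = np.array([parse_number(row[c]) for c in ("x", "y", "z")])
        case = out.setdefault(key, {})
        if name in case:
            raise ValueError(
                f"duplicate landmark {name!r} for case {key[0]!r} state {key[1]!r}")
        case[name] = point
    return {k: CephalometricLandmarkSet(v) for k, v in out.items()}


def write_landmarks(sets: dict[tuple[str, str], CephalometricLandmarkSet],
                    path: str | Path, decimals: int = 6) -> None:
    rows = []
    for (case_id, state), lm in sorted(sets.items()):
        for name, p in sorted(lm.items()):
            base, side = name, ""
            for b in BILATERAL_LANDMARKS:
                if name.startswith(b + "_"):
                    base, side = b, name[len(b) + 1:]
                    break
            rows.append({
                "case_id": case_id, "state": state, "name": base, "side": side,
                "x": f"{p[0]:.{decimals}f}", "y": f"{p[1]:.{decimals}f}",
                "z": f"{p[2]:.{decimals}f}",
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_transforms(path: str | Path) -> dict[tuple[str, str], RigidTransform]:
    """Read planning transforms: one 4x4 row-major matrix per (case, segment)."""
    df = _read_table(path)
    cols = [f"m{i}{j}" for i in range(4) for j in range(4)]
    missing = {"case_id", "segment", *cols} - set(df.columns)
    if missing:
        raise ValueError(f"transform file {path} lacks columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        m = np.array([parse_number(row[c]) for c in cols]).reshape(4, 4)
        out[(str(row["case_id"]), str(row["segment"]))] = \
            RigidTransform.from_matrix(m)
    return out


def write_transforms(transforms: dict[tuple[str, str], RigidTransform],
                     path: str | Path) -> None:
    cols = [f"m{i}{j}" for i in range(4) for j in range(4)]
    rows = []
    for (case_id, segment), t in sorted(transforms.items()):
        m = t.as_matrix().ravel()
        rows.append({"case_id": case_id, "segment": segment,
                     **{c: f"{v:.12g}" for c, v in zip(cols, m)}})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class AnalysisConfig:
    """Run configuration recorded in every report for reproducibility."""

    mode: str = "direct"                 # direct | registration
    decimals: int = 2                    # printed precision, half-up
    registration_metric: str = "ncc"     # ncc | mi
    registration_max_iterations: int = 200
    icc_form: str = "ICC(2,1)"           # two-way random, absolute agreement
    bootstrap_reps: int = 10_000
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("direct", "registration"):
            raise ValueError(f"mode must be direct|registration, got {self.mode!r}")
        for label, p in self.paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"configured path {label!r} = {p} missing")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fmt(value: float, decimals: int) -> str:
    from .pipeline import round_half_up

    return f"{round_half_up(value, decimals):.{decimals}f}"


def write_report(results, path: str | Path,
                 config: AnalysisConfig | None = None,
                 kind: str = "accuracy") -> None:
    """Write per-case rows plus Mean/Absolute-mean summary rows.

    ``results`` maps case_id -> MovementReport (one segment per file) or is a
    list of (case_id, MovementReport) pairs.  Output is deterministic: two
    runs on identical inputs produce byte-identical files.
    """
    from . import __version__
    from .pipeline import summarize_cohort

    if isinstance(results, dict):
        items = sorted(results.items())
    else:
        items = list(results)
    if not items:
        raise ValueError("cannot write an empty report")
    config = config or AnalysisConfig()
    reports = [r for _, r in items]
    summary = summarize_cohort(reports)
    dec = config.decimals

    lines = [
        f"# orthognathics {__version__} report",
        f"# kind: {kind}",
        f"# segment: {summary.segment_id}",
        f"# mode: {config.mode}",
        f"# seed: {config.seed}",
        f"# config_hash: {config.config_hash()}",
    ]
    header = ["Patient"] + [REPORT_COLUMNS[c] for c in MovementReport.COMPONENTS]
    lines.append("\t".join(header))
    for case_id, rep in items:
        lines.append("\t".join(
            [str(case_id)] + [_fmt(getattr(rep, c), dec)
                              for c in MovementReport.COMPONENTS]))
    lines.append("\t".join(
        ["Mean"] + [_fmt(summary.components[c].mean, dec)
                    for c in MovementReport.COMPONENTS]))
    lines.append("\t".join(
        ["Absolute mean"] + [_fmt(summary.components[c].abs_mean, dec)
                             for c in MovementReport.COMPONENTS]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> pd.DataFrame:
    """Parse a written report back into a DataFrame (patients and summary
    rows; metadata lines are dropped)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Patient": str})
    return df
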