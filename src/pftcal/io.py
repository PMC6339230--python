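"""Readers/writers for the on-disk formats and the session bundle.

Formats (all plain text, UTF-8, comma-separated, header row mandatory):

samples CSV     ``t,e1,...,en`` — raw eye-tracker stream, device units
fixations CSV   ``id,t_start,t_end,n_samples,e1..en``
schedule JSON   scenes with intervals and target lists (scene-percent)
reference CSV   ``e1..en,x,y`` — calPoints / refPoints pairs
model JSON      ``{degree, n, powers, coeffs_x, coeffs_y}``
report JSON     ``{error_x, error_y, avg_error, n_refpoints}``

Coordinates are serialized with 6 decimal places; a write->read->write
round trip is byte-identical.  Every simulated bundle carries a manifest
(config, seed, package version, config hash) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import ErrorReport, PolynomialGazeRegressor
from .datamodel import Fixation, ReferenceSet, SceneEntry, SceneSchedule
from .synthetic import SimulatedSession, SyntheticConfig

__all__ = [
    "read_samples_csv",
    "write_samples_csv",
    "write_fixations_csv",
    "read_fixations_csv",
    "write_schedule_json",
    "read_schedule_json",
    "write_reference_csv",
    "read_reference_csv",
    "write_model_json",
    "read_model_json",
    "write_report_json",
    "write_targets_json",
    "read_targets_json",
    "write_bundle",
    "load_bundle",
    "config_hash",
]

_FLOAT_FMT = "%.6f"


def write_samples_csv(path, samples: pd.DataFrame) -> None:
    cols = ["t"] + [c for c in samples.columns if c != "t"]
    samples[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_samples_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "t" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected header t,e1,...,en")
    return df


def write_fixations_csv(path, fixations: list[Fixation]) -> None:
    n = fixations[0].E.shape[0] if fixations else 2
    rows = [
        {
            "id": f.id,
            "t_start": f.t_start,
            "t_end": f.t_end,
            "n_samples": f.n_samples,
            **{f"e{i + 1}": f.E[i] for i in range(n)},
        }
        for f in fixations
    ]
    cols = ["id", "t_start", "t_end", "n_samples"] + [f"e{i+1}" for i in range(n)]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_fixations_csv(path) -> list[Fixation]:
    df = pd.read_csv(path)
    e_cols = [c for c in df.columns if c.startswith("e")]
    return [
        Fixation(
            id=int(r["id"]),
            E=np.array([r[c] for c in e_cols]),
            t_start=float(r["t_start"]),
            t_end=float(r["t_end"]),
            n_samples=int(r["n_samples"]),
        )
        for _, r in df.iterrows()
    ]


def _round6(x) -> float:
    return float(f"{float(x):.6f}")


def write_schedule_json(path, schedule: SceneSchedule) -> None:
    doc = {
        "scenes": [
            {
                "scene_id": e.scene_id,
                "t_start": _round6(e.t_start),
                "t_end": _round6(e.t_end),
                "stimulus": e.stimulus,
                "targets": [
                    {"x": _round6(x), "y": _round6(y)} for x, y in e.targets
                ],
            }
            for e in schedule
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_schedule_json(path) -> SceneSchedule:
    doc = json.loads(Path(path).read_text())
    return SceneSchedule(
        SceneEntry(
            scene_id=s["scene_id"],
            t_start=s["t_start"],
            t_end=s["t_end"],
            stimulus=s.get("stimulus", True),
            targets=np.array([[t["x"], t["y"]] for t in s["targets"]]),
        )
        for s in doc["scenes"]
    )


def write_reference_csv(path, refs: ReferenceSet) -> None:
    n = refs.features.shape[1]
    df = pd.DataFrame(
        np.column_stack([refs.features, refs.points]),
        columns=[f"e{i+1}" for i in range(n)] + ["x", "y"],
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_reference_csv(path, role: str = "reference") -> ReferenceSet:
    df = pd.read_csv(path)
    e_cols = [c for c in df.columns if c.startswith("e")]
    return ReferenceSet(
        features=df[e_cols].to_numpy(),
        points=df[["x", "y"]].to_numpy(),
        role=role,
    )


def write_model_json(path, model: PolynomialGazeRegressor) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def read_model_json(path) -> PolynomialGazeRegressor:
    return PolynomialGazeRegressor.from_dict(json.loads(Path(path).read_text()))


def write_report_json(path, report: ErrorReport) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=2) + "\n")


def write_targets_json(path, targets_by_scene: dict) -> None:
    doc = [
        {
            "scene_id": scene_id,
            "targets": [{"x": _round6(x), "y": _round6(y)} for x, y in pts],
        }
        for scene_id, pts in targets_by_scene.items()
    ]
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_targets_json(path) -> dict:
    doc = json.loads(Path(path).read_text())
    return {
        s["scene_id"]: np.array([[t["x"], t["y"]] for t in s["targets"]])
        for s in doc
    }


def config_hash(config_dict: dict) -> str:
    canon = json.dumps(config_dict, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_bundle(directory, session: SimulatedSession) -> None:
    """Write a complete simulated-session fixture bundle."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_samples_csv(d / "samples.csv", session.samples)
    write_schedule_json(d / "schedule.json", session.schedule)
    write_reference_csv(d / "cal_points.csv", session.cal)
    write_reference_csv(d / "ref_points.csv", session.ref)
    gt = session.ground_truth
    (d / "ground_truth.json").write_text(
        json.dumps(
            {
                "A": gt.A.tolist(),
                "b": gt.b.tolist(),
                "quad": None if gt.quad is None else gt.quad.tolist(),
                "mirrored": gt.mirrored,
                "family": gt.family,
                "planted_mapping": session.planted.tolist(),
                "gaze": [[_round6(x), _round6(y)] for x, y in session.gaze],
            },
            indent=2,
        )
        + "\n"
    )
    cfg = dataclasses.asdict(session.config)
    cfg["targets_per_scene"] = [
        int(v) for v in np.atleast_1d(cfg["targets_per_scene"])
    ]
    (d / "manifest.json").write_text(
        json.dumps(
            {
                "config": cfg,
                "seed": session.config.seed,
                "version": __version__,
                "config_hash": config_hash(cfg),
            },
            indent=2,
        )
        + "\n"
    )


def load_bundle(directory) -> dict:
    """Reload a bundle written by :func:`write_bundle`."""
    d = Path(directory)
    out = {
        "samples": read_samples_csv(d / "samples.csv"),
        "schedule": read_schedule_json(d / "schedule.json"),
        "cal": read_reference_csv(d / "cal_points.csv", role="calibration"),
        "ref": read_reference_csv(d / "ref_points.csv", role="reference"),
        "manifest": json.loads((d / "manifest.json").read_text()),
    }
    gt_path = d / "ground_truth.json"
    if gt_path.exists():
        out["ground_truth"] = json.loads(gt_path.read_text())
    return out
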