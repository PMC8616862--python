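"""Evaluation metrics and stratified multi-repetition reporting.

Weight accuracy is measured by the mean absolute error (MAE, kg) and
mean relative error (MRE, %); the virtual-uncovering quality by the Dice
overlap between binary volumes and the directed average surface distance
(ASD, mm) from the target surface to the predicted surface.  Experiments
are repeated with distinct seeds and reported as mean +- std per
(cover x position) stratum, alongside the "initial" Dice/ASD between the
covered input and the uncovered target, which is the no-model reference.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "mae",
    "mre",
    "dice",
    "surface_voxels",
    "avg_surface_distance",
    "cumulative_error_curve",
    "average_over_frames",
    "EvalCase",
    "EvalReport",
    "evaluate",
]


def mae(predictions, truths) -> float:
    """Mean absolute error in kg."""
    p = np.asarray(predictions, dtype=float).ravel()
    t = np.asarray(truths, dtype=float).ravel()
    if len(p) == 0 or len(p) != len(t):
        raise ValueError("predictions and truths must be nonempty and of equal length")
    return float(np.mean(np.abs(p - t)))


def mre(predictions, truths) -> float:
    """Mean relative error, mean(|error| / truth), as a percentage."""
    p = np.asarray(predictions, dtype=float).ravel()
    t = np.asarray(truths, dtype=float).ravel()
    if len(p) == 0 or len(p) != len(t):
        raise ValueError("predictions and truths must be nonempty and of equal length")
    if np.any(t <= 0):
        raise ValueError("true weights must be positive for MRE")
    return float(np.mean(np.abs(p - t) / t) * 100.0)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A.B| / (|A| + |B|) between binary volumes.

    The reference ``a`` must be nonempty: Dice against an empty
    reference is ill-defined and signals an upstream failure.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na = int(a.sum())
    if na == 0:
        raise ValueError("empty reference volume")
    nb = int(b.sum())
    inter = int((a & b).sum())
    return 2.0 * inter / (na + nb)


def surface_voxels(grid: np.ndarray) -> np.ndarray:
    """Boolean mask of occupied voxels with at least one unoccupied
    6-neighbor; the grid boundary counts as unoccupied."""
    g = np.asarray(grid).astype(bool)
    padded = np.pad(g, 1, constant_values=False)
    interior = np.ones_like(g)
    for axis in range(3):
        lo = np.roll(padded, 1, axis=axis)
        hi = np.roll(padded, -1, axis=axis)
        sl = tuple(slice(1, -1) for _ in range(3))
        interior &= lo[sl] & hi[sl]
    return g & ~interior


def avg_surface_distance(
    target: np.ndarray,
    predicted: np.ndarray,
    voxel_size=(1.0, 1.0, 1.0),
    symmetric: bool = False,
) -> float:
    """Directed average surface distance, in millimeters.

    Mean over target-surface voxel centers of the Euclidean distance to
    the nearest predicted-surface voxel center, with anisotropic voxel
    sizes given in meters.  ``symmetric=True`` averages both directions.
    """
    from scipy.spatial import cKDTree

    t = np.asarray(target).astype(bool)
    p = np.asarray(predicted).astype(bool)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    if not t.any() or not p.any():
        raise ValueError("surface distance undefined for an empty volume")
    size_mm = np.asarray(voxel_size, dtype=float) * 1000.0

    ts = np.argwhere(surface_voxels(t)) * size_mm
    ps = np.argwhere(surface_voxels(p)) * size_mm
    d_fwd = cKDTree(ps).query(ts)[0].mean()
    if not symmetric:
        return float(d_fwd)
    d_bwd = cKDTree(ts).query(ps)[0].mean()
    return float((d_fwd + d_bwd) / 2.0)


def cumulative_error_curve(abs_errors) -> np.ndarray:
    """Empirical CDF of absolute errors: (threshold, fraction <= threshold).

    A nondecreasing step function sampled at the sorted errors, ending at 1.
    """
    e = np.sort(np.asarray(abs_errors, dtype=float).ravel())
    if len(e) == 0:
        raise ValueError("need at least one error")
    frac = np.arange(1, len(e) + 1) / len(e)
    return np.column_stack([e, frac])


def average_over_frames(estimates, subject_ids) -> dict:
    """Arithmetic mean of per-frame weight estimates per subject."""
    est = np.asarray(estimates, dtype=float).ravel()
    ids = np.asarray(subject_ids).ravel()
    if len(est) != len(ids) or len(est) == 0:
        raise ValueError("estimates and subject ids must be nonempty and aligned")
    return {sid: float(est[ids == sid].mean()) for sid in np.unique(ids)}


# ---------------------------------------------------------------------------
# Stratified evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalCase:
    """One test case: an input volume with its labels and, when the
    uncovering stage is evaluated, the binary uncovered-patient target."""

    x: np.ndarray
    weight: float
    cover: str  # none | thin | thick
    position: str  # supine | lateral
    target: np.ndarray | None = None
    subject_id: int = 0


def _mean_std(values: list[float]) -> dict:
    out = {"mean": float(np.mean(values))}
    out["std"] = float(np.std(values, ddof=1)) if len(values) >= 2 else None
    out["n_repetitions"] = len(values)
    return out


@dataclass
class EvalReport:
    """Stratified results: per (cover, position) stratum the MAE/MRE over
    repetitions and, where targets exist, Dice/ASD with their no-model
    "initial" references; plus pooled cumulative-error curve samples."""

    strata: dict = field(default_factory=dict)
    curve: np.ndarray | None = None
    repetitions: int = 0

    def to_dict(self) -> dict:
        return {
            "repetitions": self.repetitions,
            "strata": {f"{c}/{p}": v for (c, p), v in self.strata.items()},
            "curve": self.curve.tolist() if self.curve is not None else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["cover", "position", "metric", "mean", "std"])
            for (c, p), metrics_ in sorted(self.strata.items()):
                for name, val in sorted(metrics_.items()):
                    if isinstance(val, dict):
                        writer.writerow([c, p, name, val["mean"], val.get("std")])
                    else:
                        writer.writerow([c, p, name, val, None])


def evaluate(
    fit: Callable[[int], Callable[[np.ndarray], tuple[float, np.ndarray | None]]],
    cases: list[EvalCase],
    repetitions: int = 5,
    base_seed: int = 0,
    voxel_size=(1.0, 1.0, 1.0),
) -> EvalReport:
    """Train and evaluate over several repetitions with distinct seeds.

    ``fit(seed)`` must return a predictor mapping an input volume to
    ``(weight_kg, uncovered_probability_volume_or_None)``.  For cases
    with targets the report also carries the initial Dice/ASD between
    the covered input and the target (the no-model reference).
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if not cases:
        raise ValueError("no evaluation cases")

    strata_keys = sorted({(c.cover, c.position) for c in cases})
    per_stratum: dict = {k: {"mae": [], "mre": [], "dice": [], "asd": []} for k in strata_keys}
    pooled_errors: list[float] = []

    for rep in range(repetitions):
        predictor = fit(base_seed + rep)
        preds: dict = {k: ([], []) for k in strata_keys}
        dices: dict = {k: [] for k in strata_keys}
        asds: dict = {k: [] for k in strata_keys}
        for case in cases:
            w_hat, vol = predictor(case.x)
            key = (case.cover, case.position)
            preds[key][0].append(w_hat)
            preds[key][1].append(case.weight)
            pooled_errors.append(abs(w_hat - case.weight))
            if case.target is not None and vol is not None and case.target.any():
                binary = np.asarray(vol) > 0.5
                dices[key].append(dice(case.target, binary))
                if binary.any():
                    asds[key].append(avg_surface_distance(case.target, binary, voxel_size))
        for key in strata_keys:
            p, t = preds[key]
            if p:
                per_stratum[key]["mae"].append(mae(p, t))
                per_stratum[key]["mre"].append(mre(p, t))
            if dices[key]:
                per_stratum[key]["dice"].append(float(np.mean(dices[key])))
            if asds[key]:
                per_stratum[key]["asd"].append(float(np.mean(asds[key])))

    report = EvalReport(repetitions=repetitions)
    for key in strata_keys:
        entry: dict = {}
        for name in ("mae", "mre", "dice", "asd"):
            values = per_stratum[key][name]
            if values:
                entry[name] = _mean_std(values)
        # no-model reference: covered input vs target
        init_d, init_a = [], []
        for case in cases:
            if (case.cover, case.position) != key or case.target is None or not case.target.any():
                continue
            covered_bin = np.asarray(case.x) > 0.5
            init_d.append(dice(case.target, covered_bin))
            if covered_bin.any():
                init_a.append(avg_surface_distance(case.target, covered_bin, voxel_size))
        if init_d:
            entry["initial_dice"] = float(np.mean(init_d))
        if init_a:
            entry["initial_asd"] = float(np.mean(init_a))
        if entry:
            report.strata[key] = entry
    report.curve = cumulative_error_curve(pooled_errors)
    return report
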